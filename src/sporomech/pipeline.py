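"""End-to-end orchestration: generate → inflate → sweep → analyse → cohort.

A :class:`PipelineConfig` (usually loaded from YAML) declares the material,
the cavity-pressure sweep, the rupture settings, and a list of specimens
(morphotype presets with overrides).  :func:`run_pipeline` executes every
stage for every specimen — cell inflation at turgor pressure, morphometric
attributes on the inflated state, the cavity sweep with rupture and
stress-assisted scoring, and the drying comparison — then assembles the
cohort morphospace and the three-attribute fitness landscape.  All outputs
are plain CSV/JSON (plus optional PLY/VTU meshes); a manifest records the
configuration hash and the package version so runs can be compared.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecology import build_morphospace, fitness_landscape
from .fem import MaterialSpec, MembraneModel, PressureSweep, simulate_drying
from .generate import MorphotypeSpec, build_specimen, preset
from .io import save_ply, save_vtu
from .morphometrics import specimen_attributes
from .rupture import (
    RuptureConfig,
    rupture_pressure,
    stress_assisted_score,
    strength_sweep,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    specimens: list = field(default_factory=list)   # MorphotypeSpec or dicts
    material: MaterialSpec = field(default_factory=MaterialSpec)
    p_max: float = 1.0
    step: float = 0.01
    rupture: RuptureConfig = field(default_factory=RuptureConfig)
    drying_cavity_pressure: float = 0.2
    dried_cell_pressure: float = 0.001
    seed: int = 0
    write_meshes: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            mat = MaterialSpec(**d.get("material", {}))
            sweep = d.get("sweep", {})
            rup = d.get("rupture", {})
            rupture = RuptureConfig(
                criterion=rup.get("criterion", "von_mises"),
                tensile_strength=rup.get("strength", 30.0),
                top_fraction=rup.get("top_fraction", 0.01))
            drying = d.get("drying", {})
            seed = int(d.get("seed", 0))
            specs = []
            for i, s in enumerate(d.get("specimens", [])):
                s = dict(s)
                morph = s.pop("morphotype")
                s.setdefault("rng_seed", seed + i)
                specs.append(preset(morph, **s))
            return cls(specimens=specs, material=mat,
                       p_max=float(sweep.get("p_max", 1.0)),
                       step=float(sweep.get("step", 0.01)),
                       rupture=rupture,
                       drying_cavity_pressure=float(
                           drying.get("cavity_pressure", 0.2)),
                       dried_cell_pressure=float(
                           drying.get("dried_cell_pressure", 0.001)),
                       seed=seed,
                       write_meshes=bool(d.get("write_meshes", False)))
        except (TypeError, KeyError, ValueError) as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        payload = {
            "specimens": [asdict(s) if isinstance(s, MorphotypeSpec) else s
                          for s in self.specimens],
            "material": asdict(self.material),
            "p_max": self.p_max, "step": self.step,
            "rupture": asdict(self.rupture),
            "drying": [self.drying_cavity_pressure, self.dried_cell_pressure],
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


def demo_config(seed: int = 0, p_max: float = 0.4,
                coarse: bool = True) -> PipelineConfig:
    """One specimen per morphotype at moderate resolution."""
    over = dict(n_theta=24) if coarse else {}
    specimens = [preset(m, rng_seed=seed + i, **over) for i, m in enumerate(
        ("spherical", "fusiform", "discoidal", "twisted"))]
    return PipelineConfig(specimens=specimens, p_max=p_max, seed=seed)


# --------------------------------------------------------------------- stages
def analyse_specimen(spec: MorphotypeSpec, cfg: PipelineConfig) -> dict:
    """All per-specimen stages; returns a result bundle (dict)."""
    mesh = build_specimen(spec)
    model = MembraneModel(mesh, cfg.material)
    inflated = model.solve(cfg.material.cell_pressure, 0.0)
    attrs = specimen_attributes(mesh, inflated)

    sweep = PressureSweep()
    x = inflated.positions
    pressures = np.arange(0.0, cfg.p_max + 0.5 * cfg.step, cfg.step)
    for p in pressures:
        st = model.solve(cfg.material.cell_pressure, float(p), x0=x)
        if not st.converged and len(sweep.states):
            logger.warning("%s: sweep truncated at %.2f MPa", spec.morphotype, p)
            break
        sweep.states.append(st)
        x = st.positions
    result = rupture_pressure(sweep, cfg.rupture, expected_p_max=cfg.p_max)
    table = strength_sweep(sweep)

    apex = np.nan
    if result.ruptured:
        k = int(round(result.rupture_pressure / cfg.step))
        apex = stress_assisted_score(sweep[k], mesh)
    result.stress_assisted_score = apex

    dry_a, dry_b = simulate_drying(
        mesh, cfg.material, cavity_pressure=cfg.drying_cavity_pressure,
        dried_cell_pressure=cfg.dried_cell_pressure, validate=False)

    return dict(spec=spec, mesh=mesh, inflated=inflated, sweep=sweep,
                attributes=attrs, rupture=result, strength_table=table,
                apex_score=apex, drying=(dry_a, dry_b))


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage for every specimen and write the report bundle.

    Outputs under ``outdir``: ``attributes.csv`` (one row per specimen,
    seven descriptors), ``rupture.csv`` (criterion × strength table),
    ``fitness.csv`` (normalized attributes, fitness, niche),
    ``summary.json`` (morphospace variance, silhouettes, drying signs) and
    ``manifest.json``.  Stage failures are recorded in the manifest;
    completed stages keep their outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config_sha256": cfg.digest(),
                "seed": cfg.seed, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "failed_stage": None}
    bundles = []
    try:
        for i, spec in enumerate(cfg.specimens):
            name = f"{spec.morphotype}_{i}"
            logger.info("specimen %s", name)
            b = analyse_specimen(spec, cfg)
            b["name"] = name
            bundles.append(b)
            if cfg.write_meshes:
                save_ply(b["mesh"], outdir / f"{name}.ply")
                st = b["sweep"][-1]
                save_vtu(b["mesh"], outdir / f"{name}.vtu",
                         cell_data={"von_mises": st.von_mises,
                                    "s1": st.principal_stresses[:, 0]},
                         vertices=st.positions)
    except Exception as err:                      # partial outputs retained
        manifest["failed_stage"] = f"specimen {len(bundles)}: {err}"
        logger.error("pipeline stage failed: %s", err)

    summary = {}
    if bundles:
        attr = pd.DataFrame([b["attributes"].as_dict() for b in bundles],
                            index=[b["name"] for b in bundles])
        attr.to_csv(outdir / "attributes.csv")
        rows = []
        for b in bundles:
            t = b["strength_table"].copy()
            t.insert(0, "specimen", b["name"])
            rows.append(t)
        pd.concat(rows).to_csv(outdir / "rupture.csv", index=False)

        fit_in = pd.DataFrame({
            "cavity_volume": attr["cavity_volume"],
            "rupture_pressure": [b["rupture"].rupture_pressure
                                 for b in bundles],
            "stress_assisted_score": [b["apex_score"] for b in bundles],
        }, index=attr.index)
        # specimens that never ruptured within the sweep carry no dispersal
        # attributes; they are censored out of the landscape
        fit_valid = fit_in.dropna()
        if len(fit_valid) >= 2:
            try:
                fit = fitness_landscape(fit_valid)
                fit.to_csv(outdir / "fitness.csv")
                summary["niches"] = fit["niche"].to_dict()
            except ValueError as err:
                # degenerate cohort (constant attribute): landscape undefined
                summary["fitness"] = f"skipped: {err}"
        else:
            summary["fitness"] = "skipped: fewer than 2 ruptured specimens"

        if len(bundles) >= 3:
            ms = build_morphospace(attr, ks=(min(4, len(bundles) - 1),))
            summary["variance_explained"] = \
                ms.explained_variance_ratio.tolist()
            summary["upgma_labels"] = {n: int(l) for n, l in
                                       zip(attr.index, ms.upgma_labels)}
        summary["drying_max_stress"] = {
            b["name"]: {"turgid": float(np.nanmax(b["drying"][0].von_mises)),
                        "dried": float(np.nanmax(b["drying"][1].von_mises))}
            for b in bundles}
        summary["rupture_pressure"] = {
            b["name"]: b["rupture"].rupture_pressure for b in bundles}
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"bundles": bundles, "summary": summary, "manifest": manifest}
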
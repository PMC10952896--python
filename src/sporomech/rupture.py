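"""Failure criteria, rupture-pressure estimation and apical stress scoring.

Two classical failure criteria bracket the unknown material behaviour of
the fossil wall tissue: von Mises (ductile, like hydrated cell walls) and
maximum principal stress (brittle, like dry lignified walls).  To avoid
single-element numerical artefacts, the organ is considered ruptured at the
smallest cavity pressure at which the top 1% most stressed wall elements
reach the tensile strength (30 MPa by default, the consistent value for
leaf-like tissue; a 20–40 MPa range is swept for robustness).

The stress-assisted-rupture score asks whether stress concentrates at the
sporangium apex — where valvate dehiscence starts — by comparing the mean
stress of apical elements against the organ-wide mean; positive values mean
the morphology itself funnels stress toward the opening site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import PressureSweep, StressState
from .mesh import SIDE_INNER, SIDE_OUTER, CellularShellMesh

NOT_RUPTURED = np.nan

CRITERIA = ("von_mises", "max_stress")


def von_mises(s1, s2, s3):
    """Equivalent (von Mises) stress from three principal stresses.

    ``sqrt(((s1-s2)^2 + (s2-s3)^2 + (s1-s3)^2)/2)``; permutation-invariant,
    zero iff the state is hydrostatic.  Accepts scalars or arrays.
    """
    s1, s2, s3 = np.asarray(s1, float), np.asarray(s2, float), np.asarray(s3, float)
    return np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s1 - s3) ** 2))


def max_stress(s1, s2, s3):
    """Maximum principal stress (signed)."""
    return np.maximum(np.maximum(np.asarray(s1, float), s2), s3)


@dataclass
class RuptureConfig:
    criterion: str = "von_mises"
    tensile_strength: float = 30.0       # MPa
    top_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.tensile_strength <= 0:
            raise ValueError("tensile strength must be positive")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class RuptureResult:
    rupture_pressure: float              # MPa; NaN = never ruptured in sweep
    ruptured: bool
    criterion: str
    tensile_strength: float
    pressures: np.ndarray = field(repr=False, default=None)
    cv_trace: np.ndarray = field(repr=False, default=None)
    lower_bound: bool = False            # True when the sweep was truncated
    stress_assisted_score: float | None = None


# --------------------------------------------------------------------- helpers
def _criterion_values(state: StressState, criterion: str) -> np.ndarray:
    p = state.principal_stresses
    keep = np.isfinite(p[:, 0])
    p = p[keep]
    if criterion == "von_mises":
        return von_mises(p[:, 0], p[:, 1], p[:, 2])
    return max_stress(p[:, 0], p[:, 1], p[:, 2])


def _top_quantile_value(values: np.ndarray, top_fraction: float) -> float:
    """The k-th largest value with k = ceil(top_fraction * n) (ties by index)."""
    n = len(values)
    k = max(1, int(np.ceil(top_fraction * n)))
    return float(np.partition(values, n - k)[n - k])


# ------------------------------------------------------------------ operations
def stress_cv(state: StressState) -> float:
    """Coefficient of variation (population SD / mean) of von Mises stress."""
    vm = state.stresses()
    if len(vm) < 2:
        raise ValueError("stress CV needs at least 2 wall elements")
    m = vm.mean()
    return float(vm.std() / m) if m != 0 else np.nan


def rupture_pressure(sweep: PressureSweep, config: RuptureConfig | None = None,
                     expected_p_max: float | None = None) -> RuptureResult:
    """Smallest sweep pressure at which the top stress quantile hits strength.

    Deterministic: the threshold element is the ceil(top_fraction·n)-th
    largest criterion stress among non-membrane elements.  If the sweep was
    truncated before ``expected_p_max`` and no rupture was found, the result
    is flagged as a lower bound.
    """
    config = config or RuptureConfig()
    if len(sweep) < 2:
        raise ValueError("rupture_pressure needs a sweep with >= 2 states")
    pressures = sweep.pressures
    cv = np.array([stress_cv(s) for s in sweep.states])
    p_rupture = NOT_RUPTURED
    ruptured = False
    for state in sweep.states:
        stat = _top_quantile_value(
            _criterion_values(state, config.criterion), config.top_fraction)
        if stat >= config.tensile_strength:
            p_rupture = float(state.cavity_pressure)
            ruptured = True
            break
    truncated = (expected_p_max is not None
                 and pressures[-1] < expected_p_max - 1e-12)
    return RuptureResult(
        rupture_pressure=p_rupture, ruptured=ruptured,
        criterion=config.criterion, tensile_strength=config.tensile_strength,
        pressures=pressures, cv_trace=cv,
        lower_bound=(not ruptured) and truncated)


def stress_assisted_score(state: StressState, mesh: CellularShellMesh) -> float:
    """Apical minus organ-wide mean von Mises stress (MPa) at one state.

    Elements are taken in the deformed configuration, centered at the
    cavity centroid with the organ axis along +X.  The apical candidates
    lie inside the elliptical cylinder about X with semi-axes equal to half
    the +Y extent and half the |−Z| extent of the wall elements, in the
    upper half of the X range; of these, the wall surface (inner or outer)
    with the larger mean stress is kept — the surface most likely to tear.
    Positive score: stress concentrates at the apex.
    """
    x = state.positions
    keep = ~mesh.is_membrane
    cent = mesh.face_centroids(x)
    # center at the cavity centroid (area-weighted over the cavity boundary)
    cm = mesh.cavity_face_mask
    w = mesh.face_areas(x)[cm]
    origin = (cent[cm] * w[:, None]).sum(axis=0) / w.sum()
    rel = cent - origin

    el = rel[keep]
    vm_all = state.von_mises[keep]
    a_y = el[:, 1].max() / 2.0
    a_z = abs(el[:, 2].min()) / 2.0
    if a_y <= 0 or a_z <= 0:
        raise ValueError("degenerate transverse extents; check centering")
    inside = (el[:, 1] / a_y) ** 2 + (el[:, 2] / a_z) ** 2 <= 1.0
    x_mid = 0.5 * (el[:, 0].max() + el[:, 0].min())
    superior = inside & (el[:, 0] > x_mid)

    side = mesh.side[keep]
    apical_outer = superior & (side == SIDE_OUTER)
    apical_inner = superior & (side == SIDE_INNER)
    if not apical_outer.any() and not apical_inner.any():
        raise ValueError(
            "empty apical element set: check that the mesh is centered at "
            "the cavity centroid and the longitudinal axis is +X")
    mean_out = vm_all[apical_outer].mean() if apical_outer.any() else -np.inf
    mean_in = vm_all[apical_inner].mean() if apical_inner.any() else -np.inf
    apical_mean = max(mean_out, mean_in)
    return float(apical_mean - vm_all.mean())


def strength_sweep(sweep: PressureSweep,
                   criteria=CRITERIA,
                   strengths=np.arange(20.0, 40.0 + 1e-9, 5.0),
                   top_fraction: float = 0.01) -> pd.DataFrame:
    """Rupture pressure for every (criterion, tensile strength) combination."""
    rows = []
    for crit in criteria:
        for sy in strengths:
            res = rupture_pressure(sweep, RuptureConfig(
                criterion=crit, tensile_strength=float(sy),
                top_fraction=top_fraction))
            rows.append(dict(criterion=crit, tensile_strength=float(sy),
                             rupture_pressure=res.rupture_pressure,
                             ruptured=res.ruptured))
    return pd.DataFrame(rows)
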
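"""Shared fixtures: synthetic specimens and their (expensive) FEM runs.

Simulation fixtures are session-scoped so that the pressure sweeps are
computed once and shared by the morphometric, rupture and acceptance
tests.  Problem sizes follow the generator presets (fossil-scale cells on
sub-millimetre organs); sweeps stop at 0.45 MPa, above every preset's
rupture pressure at the default 30 MPa strength.
"""

from __future__ import annotations

import numpy as np
import pytest

import sporomech as sm

SWEEP_PMAX = 0.45
SWEEP_STEP = 0.01


@pytest.fixture(scope="session")
def material() -> sm.MaterialSpec:
    return sm.MaterialSpec()


def _morphotype_run(morph: str, material: sm.MaterialSpec, seed: int = 0):
    mesh = sm.build_specimen(sm.preset(morph, rng_seed=seed))
    model = sm.MembraneModel(mesh, material)
    inflated = model.solve(material.cell_pressure, 0.0)
    assert inflated.converged, f"{morph}: cell inflation did not converge"
    sweep = sm.pressurize_cavity_sweep(
        mesh, material, p_max=SWEEP_PMAX, step=SWEEP_STEP,
        x0=inflated.positions, validate=False)
    result = sm.rupture_pressure(sweep, expected_p_max=SWEEP_PMAX)
    return dict(morph=morph, mesh=mesh, model=model, inflated=inflated,
                sweep=sweep, rupture=result)


@pytest.fixture(scope="session")
def spherical_run(material):
    return _morphotype_run("spherical", material)


@pytest.fixture(scope="session")
def fusiform_run(material):
    return _morphotype_run("fusiform", material)


@pytest.fixture(scope="session")
def discoidal_run(material):
    return _morphotype_run("discoidal", material)


@pytest.fixture(scope="session")
def twisted_run(material):
    return _morphotype_run("twisted", material)


@pytest.fixture(scope="session")
def drying_runs(material):
    """Turgid vs dried states for the drying-sign comparisons."""
    out = {}
    for morph in ("spherical", "fusiform", "discoidal"):
        mesh = sm.build_specimen(sm.preset(morph, rng_seed=0))
        out[morph] = (mesh, *sm.simulate_drying(mesh, material,
                                                validate=False))
    return out


@pytest.fixture(scope="session")
def untwisted_torsion(material):
    """Inflation + cavity states of an untilted cylindrical specimen."""
    spec = sm.preset("cylindrical", rng_seed=0, file_tilt=0.0)
    mesh = sm.build_specimen(spec)
    model = sm.MembraneModel(mesh, material)
    inflated = model.solve(material.cell_pressure, 0.0)
    cavity = model.solve(material.cell_pressure, 0.3, x0=inflated.positions)
    return mesh, inflated, cavity


@pytest.fixture(scope="session")
def cohort_attributes():
    """15-specimen synthetic cohort (3 morphotypes × 5 seeds).

    Attributes are measured on the generated (reference) geometry — shape
    recovery does not require the inflation stage.
    """
    import pandas as pd
    rows, labels, names = [], [], []
    for g, morph in enumerate(("spherical", "discoidal", "twisted")):
        for seed in range(5):
            mesh = sm.build_specimen(sm.preset(morph, rng_seed=seed))
            rows.append(sm.specimen_attributes(mesh).as_dict())
            labels.append(g)
            names.append(f"{morph}_{seed}")
    return pd.DataFrame(rows, index=names), np.array(labels)


@pytest.fixture(scope="session")
def laplace_sphere_sweep(material):
    """Cavity sweep of the closed thin sphere R=500 μm, t=8 μm (0→1 MPa)."""
    shell = sm.icosphere_shell(500.0, subdivisions=3)
    mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0)
    return shell, sm.pressurize_cavity_sweep(shell, mat, p_max=1.0, step=0.01)
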
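"""Membrane FEM: load consistency, invariances, convergence order."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import sporomech as sm
from sporomech.fem import MembraneModel
from sporomech.mesh import MeshError


@pytest.fixture(scope="module")
def small_capsule():
    return sm.capsule_shell(100.0, 200.0, count=(10, 10))


class TestStatics:
    def test_unloaded_state_has_zero_stress(self, small_capsule):
        mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0,
                              cavity_pressure=0.0)
        st = sm.solve_equilibrium(small_capsule, mat)
        assert st.converged
        assert np.allclose(st.positions, small_capsule.vertices)
        assert np.nanmax(st.von_mises) < 1e-9

    def test_follower_loads_self_equilibrated(self):
        """Pressure on closed compartments exerts no net force or torque."""
        mesh = sm.build_specimen(sm.preset("spherical", rng_seed=0))
        model = MembraneModel(mesh, sm.MaterialSpec())
        _, f_load, _ = model.forces(mesh.vertices, p_cell=0.5, p_cav=0.3)
        scale = np.linalg.norm(f_load)
        assert np.linalg.norm(f_load.sum(axis=0)) < 1e-6 * scale
        c = mesh.vertices.mean(axis=0)
        torque = np.cross(mesh.vertices - c, f_load).sum(axis=0)
        assert np.linalg.norm(torque) < 1e-6 * scale * 100.0

    def test_equilibrium_balances_elastic_and_pressure_forces(self,
                                                              small_capsule):
        mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0)
        model = MembraneModel(small_capsule, mat)
        st = model.solve(0.0, 0.2)
        assert st.converged
        r, f_load, _ = model.forces(st.positions, 0.0, 0.2)
        assert np.linalg.norm(r) <= 1.1e-3 * np.linalg.norm(f_load)

    def test_rotation_invariance_of_stresses(self, small_capsule):
        mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0)
        st0 = sm.solve_equilibrium(small_capsule, mat)
        R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
        rotated = small_capsule.copy()
        rotated.vertices = small_capsule.vertices @ R.T
        st1 = sm.solve_equilibrium(rotated, mat)
        assert np.nanmax(np.abs(st1.principal_stresses
                                - st0.principal_stresses)) < 1e-6

    def test_sphere_benchmark_converges_under_refinement(self):
        """Laplace-law error at least halves from icosphere level 3 to 4.

        The constant-strain membrane converges between first and second
        order on the uniform sphere; the error must drop by at least the
        first-order factor (×2 within 30%).
        """
        mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0,
                              cavity_pressure=0.2)
        errs = []
        for sub in (3, 4):
            shell = sm.icosphere_shell(200.0, subdivisions=sub)
            st = sm.solve_equilibrium(shell, mat, tol=1e-5)
            mean = np.nanmean(0.5 * (st.principal_stresses[:, 0]
                                     + st.principal_stresses[:, 1]))
            # compare against the finite-strain closed form, not the
            # linearized pR/2t, to isolate the discretization error
            errs.append(abs(mean - _sphere_cauchy_closed_form(
                0.2, 200.0, 8.0)))
        assert errs[0] / errs[1] >= 1.4

    def test_non_watertight_mesh_rejected(self):
        mesh = sm.build_specimen(sm.preset("spherical", rng_seed=0))
        broken = mesh.copy()
        keep = np.ones(broken.n_faces, bool)
        keep[np.where(broken.cavity_face_mask)[0][0]] = False
        broken.faces = broken.faces[keep]
        broken.cell_id = broken.cell_id[keep]
        broken.side = broken.side[keep]
        broken.cell_id2 = broken.cell_id2[keep]
        with pytest.raises(MeshError):
            MembraneModel(broken, sm.MaterialSpec())

    def test_material_validation(self):
        with pytest.raises(ValueError):
            sm.MaterialSpec(youngs_modulus=-1)
        with pytest.raises(ValueError):
            sm.MaterialSpec(poisson_ratio=0.5)
        with pytest.raises(ValueError):
            sm.MaterialSpec(cell_pressure=-0.1)


def _sphere_cauchy_closed_form(p, R0, t0, E=100.0, nu=0.3):
    """Cauchy membrane stress of an inflated StVK sphere (exact solve).

    Solves p = 2 t0 S(λ)/(λ R0) for the stretch λ, with the plane-stress
    StVK response S = E/(1-ν)·(λ²-1)/2 and thickness stretch
    λ3 = sqrt(1 - 2ν/(1-ν)·(λ²-1)); returns σ = S/λ3.
    """
    from scipy.optimize import brentq
    k = E / (1.0 - nu)

    def resid(lam):
        S = 0.5 * k * (lam ** 2 - 1.0)
        return 2.0 * t0 * S / (lam * R0) - p

    lam = brentq(resid, 1.0 + 1e-12, 2.0)
    S = 0.5 * k * (lam ** 2 - 1.0)
    lam3 = np.sqrt(1.0 - 2.0 * nu / (1.0 - nu) * (lam ** 2 - 1.0))
    return S / lam3


class TestSweep:
    def test_zero_pmax_equals_single_equilibrium(self, small_capsule):
        mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0)
        sweep = sm.pressurize_cavity_sweep(small_capsule, mat, p_max=0.0)
        single = sm.solve_equilibrium(small_capsule, mat)
        assert len(sweep) == 1
        assert np.allclose(sweep[0].positions, single.positions)

    def test_pressures_uniform_and_increasing(self, small_capsule):
        mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0)
        sweep = sm.pressurize_cavity_sweep(small_capsule, mat, p_max=0.05,
                                           step=0.01)
        p = sweep.pressures
        assert len(p) == 6
        assert np.allclose(np.diff(p), 0.01)

    def test_max_stress_monotone_under_loading(self):
        shell = sm.icosphere_shell(200.0, subdivisions=2)
        mat = sm.MaterialSpec(thickness=8.0, cell_pressure=0.0)
        sweep = sm.pressurize_cavity_sweep(shell, mat, p_max=0.1, step=0.02)
        peaks = [np.nanmax(s.von_mises) for s in sweep.states]
        assert np.all(np.diff(peaks) > 0)


class TestDrying:
    def test_unloaded_limit_relaxes_stresses(self):
        """Deflating the cells with an unpressurized cavity unloads the wall.

        The bulged membranes retain a small locked-in self-stress (they do
        not snap back through the flat configuration), so the dried state
        is compared against the turgid one: the stress field must collapse
        by an order of magnitude.
        """
        spec = sm.preset("cylindrical", rng_seed=0, n_theta=16,
                         cell_rows=2, cell_cols=4, height=120, width=80,
                         jitter_sigma=0.0)
        mesh = sm.build_specimen(spec)
        mat = sm.MaterialSpec(cell_pressure=0.5)
        turgid, dried = sm.simulate_drying(mesh, mat, cavity_pressure=0.0,
                                           dried_cell_pressure=1e-3,
                                           tol=1e-5, validate=False)
        assert np.nanmax(dried.von_mises) < 0.1 * np.nanmax(turgid.von_mises)
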
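"""Geometrically nonlinear triangular-membrane FEM for pressurized shells.

The sporangium wall is modeled as a constant-strain-triangle membrane
(no bending stiffness) with a St. Venant–Kirchhoff plane-stress material.
Loads are follower pressures: every cell compartment carries its turgor
pressure on all of its faces, and the sporangial cavity carries a separate
pressure on the cavity boundary (inner faces plus the basal membrane);
pressure forces are recomputed from the deformed face areas and normals at
every iteration, so the load follows the surface.

Equilibria are found by semi-implicit dynamic relaxation: a backward-Euler
step of a mass-scaled, damped pseudo-dynamic system, with kinetic-energy
damping (velocities are zeroed when the kinetic energy peaks) and with
rigid-body translation/rotation projected out of the motion at every
iteration (the shells float freely; there are no Dirichlet constraints).
Convergence is declared when the residual force norm drops below 10⁻³ of
the applied load norm.

Units: μm, MPa; forces are MPa·μm² (μN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .mesh import SIDE_ANTICLINAL, SIDE_INNER, SIDE_MEMBRANE, SIDE_OUTER, \
    CellularShellMesh, MeshError, _check_closed

logger = logging.getLogger(__name__)


@dataclass
class MaterialSpec:
    """Elastic constants, wall thickness and pressure assignments.

    ``youngs_modulus`` (MPa) and ``poisson_ratio`` are the standard plant
    cell-wall estimates (100 MPa, 0.3); ``thickness`` is the membrane
    thickness of each FEM surface (μm) — the thickness of the cell wall
    material itself, not the 8 μm depth of the cell layer.  ``cell_pressure``
    is the turgor pressure applied inside every cell compartment and
    ``cavity_pressure`` the pressure inside the sporangial cavity.
    """

    youngs_modulus: float = 100.0
    poisson_ratio: float = 0.3
    thickness: float = 0.5
    cell_pressure: float = 0.5
    cavity_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.cell_pressure < 0 or self.cavity_pressure < 0:
            raise ValueError("pressures must be non-negative")


@dataclass
class StressState:
    """Converged (or best-effort) equilibrium at one load level."""

    positions: np.ndarray           # (V, 3) deformed vertex positions, μm
    principal_stresses: np.ndarray  # (F, 3) Cauchy σ1 ≥ σ2 ≥ σ3, MPa; NaN on membrane
    von_mises: np.ndarray           # (F,) MPa; NaN on membrane faces
    cavity_pressure: float
    cell_pressure: float
    converged: bool
    residual: float = np.nan        # final |residual| / |load|
    n_iterations: int = 0

    def stresses(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Finite von Mises values (membrane faces excluded)."""
        vm = self.von_mises if mask is None else self.von_mises[mask]
        return vm[np.isfinite(vm)]


@dataclass
class PressureSweep:
    """Ordered stress states over a uniform cavity-pressure ramp."""

    states: list[StressState] = field(default_factory=list)

    @property
    def pressures(self) -> np.ndarray:
        return np.array([s.cavity_pressure for s in self.states])

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i) -> StressState:
        return self.states[i]


# =========================================================================== #
class MembraneModel:
    """Precomputed FEM discretization of one cellular shell mesh."""

    def __init__(self, mesh: CellularShellMesh, material: MaterialSpec,
                 validate: bool = True):
        self.mesh = mesh
        self.material = material
        if validate:
            mesh.validate(check_cavity=True)
            self._check_compartments()

        v = mesh.vertices
        f = mesh.faces
        self.nV = len(v)
        self.nF = len(f)

        # reference local frames: Dm columns are the 2-D edge coordinates
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        t1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n, axis=1, keepdims=True)
        if np.any(nn == 0):
            raise MeshError("degenerate reference triangle")
        t2 = np.cross(n / nn, t1)
        d11 = np.einsum("ij,ij->i", e1, t1)
        d12 = np.einsum("ij,ij->i", e2, t1)
        d22 = np.einsum("ij,ij->i", e2, t2)
        det = d11 * d22
        self.Bm = np.empty((self.nF, 2, 2))
        self.Bm[:, 0, 0] = d22 / det
        self.Bm[:, 0, 1] = -d12 / det
        self.Bm[:, 1, 0] = 0.0
        self.Bm[:, 1, 1] = d11 / det
        self.A0 = 0.5 * np.abs(det)

        E, nu = material.youngs_modulus, material.poisson_ratio
        self.k_ps = E / (1.0 - nu * nu)
        self.nu = nu
        self.t = material.thickness

        # follower-load coefficients: multiple of cell / cavity pressure per face
        side = mesh.side
        cell2 = mesh.cell_id2
        self.coef_cell = np.zeros(self.nF)
        self.coef_cell[side == SIDE_OUTER] = 1.0
        self.coef_cell[side == SIDE_INNER] = -1.0
        rim = (side == SIDE_ANTICLINAL) & (cell2 < 0)
        self.coef_cell[rim] = 1.0
        self.coef_cav = np.where((side == SIDE_INNER) | (side == SIDE_MEMBRANE),
                                 1.0, 0.0)

        # scatter matrix: (V, 3F) summing per-corner forces to vertices
        rows = f.T.ravel()
        cols = np.arange(3 * self.nF)
        self.scatter = sp.csr_matrix(
            (np.ones(3 * self.nF), (rows, cols)), shape=(self.nV, 3 * self.nF))

        # dynamic-relaxation mass scaling (unit pseudo-time step)
        k_face = self.k_ps * self.t * self.A0 * np.einsum(
            "fij,fij->f", self.Bm, self.Bm)
        k_vert = self.scatter @ np.tile(k_face, 3)
        self.mass0 = 2.0 * np.maximum(k_vert, k_vert.max() * 1e-6)

        self.is_membrane = side == SIDE_MEMBRANE

    # ------------------------------------------------------------------ loads
    def _check_compartments(self) -> None:
        m = self.mesh
        for c in m.cells:
            fi, s = m.compartment_faces(int(c))
            faces = m.faces[fi].copy()
            neg = s < 0
            faces[neg] = faces[neg][:, [0, 2, 1]]
            try:
                _check_closed(faces, allow_pinched=True)
            except MeshError as err:
                raise MeshError(f"cell {c}: compartment not watertight "
                                f"({err})") from err

    def forces(self, x: np.ndarray, p_cell: float, p_cav: float):
        """Elastic + pressure corner forces; returns (f_total, f_load, aux)."""
        f = self.mesh.faces
        e1 = x[f[:, 1]] - x[f[:, 0]]
        e2 = x[f[:, 2]] - x[f[:, 0]]

        # deformation gradient F = [e1 e2] @ Bm   -> (F, 3, 2)
        F0 = e1[:, :, None] * self.Bm[:, None, 0, :] \
            + e2[:, :, None] * self.Bm[:, None, 1, :]
        # Green strain (2x2 symmetric)
        C11 = np.einsum("fi,fi->f", F0[:, :, 0], F0[:, :, 0])
        C22 = np.einsum("fi,fi->f", F0[:, :, 1], F0[:, :, 1])
        C12 = np.einsum("fi,fi->f", F0[:, :, 0], F0[:, :, 1])
        Exx = 0.5 * (C11 - 1.0)
        Eyy = 0.5 * (C22 - 1.0)
        Exy = 0.5 * C12
        # plane-stress St. Venant–Kirchhoff 2nd Piola–Kirchhoff stress
        Sxx = self.k_ps * (Exx + self.nu * Eyy)
        Syy = self.k_ps * (Eyy + self.nu * Exx)
        Sxy = self.k_ps * (1.0 - self.nu) * Exy
        # P = F S  (3x2)
        P1 = F0[:, :, 0] * Sxx[:, None] + F0[:, :, 1] * Sxy[:, None]
        P2 = F0[:, :, 0] * Sxy[:, None] + F0[:, :, 1] * Syy[:, None]
        # H = A0 t P Bm^T ; columns are minus the forces on vertices 1, 2
        w = (self.A0 * self.t)[:, None]
        H1 = w * (P1 * self.Bm[:, 0, 0, None] + P2 * self.Bm[:, 0, 1, None])
        H2 = w * (P1 * self.Bm[:, 1, 0, None] + P2 * self.Bm[:, 1, 1, None])
        corner = np.empty((3, self.nF, 3))
        corner[1] = -H1
        corner[2] = -H2
        corner[0] = H1 + H2

        # follower pressure on deformed areas
        G = 0.5 * np.cross(e1, e2)          # area vectors
        pf = (self.coef_cell * p_cell + self.coef_cav * p_cav)[:, None] * G
        load_corner = np.broadcast_to((pf / 3.0)[None], (3, self.nF, 3))
        f_load = self.scatter @ load_corner.reshape(3 * self.nF, 3)
        f_elastic = self.scatter @ corner.reshape(3 * self.nF, 3)
        aux = (F0, Exx, Eyy, Sxx, Syy, Sxy, C11, C22, C12)
        return f_elastic + f_load, f_load, aux

    # ------------------------------------------------------------------ solve
    def solve(self, p_cell: float, p_cav: float,
              x0: np.ndarray | None = None, tol: float = 1e-3,
              max_iter: int = 100_000) -> StressState:
        x = (self.mesh.vertices if x0 is None else x0).copy()
        v = np.zeros_like(x)
        # force scale for the zero-load limit of the relative residual
        f_scale = self.k_ps * self.t * np.sqrt(self.A0.sum())
        mass = self.mass0.copy()
        damp = 0.02
        x_start = x.copy()
        restarts = 0
        ke_prev = 0.0
        res_rel = np.inf
        it = 0
        check_every = 5
        while it < max_iter:
            it += 1
            r, f_load, _ = self.forces(x, p_cell, p_cav)
            load_norm = np.linalg.norm(f_load)
            ref = max(load_norm, 1e-6 * f_scale)
            if it % check_every == 0 or it == 1:
                res_rel = np.linalg.norm(r) / ref
                if not np.isfinite(res_rel) or res_rel > 1e7:
                    # diverged: restart from scratch with heavier masses
                    restarts += 1
                    if restarts > 4:
                        break
                    mass *= 4.0
                    x = x_start.copy()
                    v[:] = 0.0
                    ke_prev = 0.0
                    continue
                if res_rel < tol:
                    break
            a = r / mass[:, None]
            v = (v + a) / (1.0 + damp)
            v = _project_rigid(x, v, mass)
            ke = float(np.einsum("ij,ij->", v * mass[:, None], v))
            if ke < ke_prev:
                v[:] = 0.0
                ke_prev = 0.0
            else:
                ke_prev = ke
            x = x + v
        converged = res_rel < tol
        if not converged:
            logger.warning("dynamic relaxation did not converge: "
                           "residual %.3g after %d iterations", res_rel, it)
        return self._stress_state(x, p_cell, p_cav, converged, res_rel, it)

    # ----------------------------------------------------------------- stress
    def _stress_state(self, x, p_cell, p_cav, converged, res, it) -> StressState:
        _, _, aux = self.forces(x, p_cell, p_cav)
        F0, Exx, Eyy, Sxx, Syy, Sxy, C11, C22, C12 = aux
        # Cauchy stress: nonzero eigenvalues of (S C)/J with J = λ1 λ2 λ3
        detC = np.maximum(C11 * C22 - C12 * C12, 1e-300)
        area_stretch = np.sqrt(detC)
        E33 = -(self.nu / (1.0 - self.nu)) * (Exx + Eyy)
        lam3 = np.sqrt(np.maximum(1.0 + 2.0 * E33, 1e-6))
        J = area_stretch * lam3
        # M = S @ C (2x2, eigenvalues real)
        M11 = Sxx * C11 + Sxy * C12
        M12 = Sxx * C12 + Sxy * C22
        M21 = Sxy * C11 + Syy * C12
        M22 = Sxy * C12 + Syy * C22
        tr = M11 + M22
        det = M11 * M22 - M12 * M21
        disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
        s_a = 0.5 * (tr + disc) / J
        s_b = 0.5 * (tr - disc) / J
        zeros = np.zeros_like(s_a)
        principal = np.sort(np.stack([s_a, s_b, zeros], axis=1), axis=1)[:, ::-1]
        s1, s2, s3 = principal[:, 0], principal[:, 1], principal[:, 2]
        vm = np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s1 - s3) ** 2))
        principal = principal.copy()
        principal[self.is_membrane] = np.nan
        vm = vm.copy()
        vm[self.is_membrane] = np.nan
        return StressState(positions=x, principal_stresses=principal,
                           von_mises=vm, cavity_pressure=p_cav,
                           cell_pressure=p_cell, converged=converged,
                           residual=float(res), n_iterations=it)


def _project_rigid(x: np.ndarray, v: np.ndarray, mass: np.ndarray) -> np.ndarray:
    """Remove rigid translation and rotation from a velocity field."""
    m = mass[:, None]
    M = mass.sum()
    c = (m * x).sum(axis=0) / M
    q = x - c
    v_mean = (m * v).sum(axis=0) / M
    v = v - v_mean
    L = (mass[:, None] * np.cross(q, v)).sum(axis=0)
    qq = (mass * np.einsum("ij,ij->i", q, q))
    inertia = np.diag([qq.sum()] * 3) - (q * mass[:, None]).T @ q
    try:
        omega = np.linalg.solve(inertia, L)
    except np.linalg.LinAlgError:
        return v
    return v - np.cross(omega, q)


# =========================================================================== #
def solve_equilibrium(mesh: CellularShellMesh, material: MaterialSpec,
                      x0: np.ndarray | None = None, tol: float = 1e-3,
                      max_iter: int = 100_000, validate: bool = True
                      ) -> StressState:
    """Static equilibrium of the shell under its cell and cavity pressures."""
    model = MembraneModel(mesh, material, validate=validate)
    return model.solve(material.cell_pressure, material.cavity_pressure,
                       x0=x0, tol=tol, max_iter=max_iter)


def pressurize_cavity_sweep(mesh: CellularShellMesh, material: MaterialSpec,
                            p_max: float = 1.0, step: float = 0.01,
                            x0: np.ndarray | None = None, tol: float = 1e-3,
                            max_iter: int = 100_000, validate: bool = True
                            ) -> PressureSweep:
    """Ramp the cavity pressure from 0 to ``p_max`` in uniform increments.

    Cell pressure is held constant throughout; every step warm-starts from
    the previous converged geometry.  On divergence the sweep is truncated
    with a warning and the states obtained so far are returned.
    """
    model = MembraneModel(mesh, material, validate=validate)
    pressures = np.arange(0.0, p_max + 0.5 * step, step) if p_max > 0 \
        else np.array([0.0])
    sweep = PressureSweep()
    x = x0
    for p in pressures:
        state = model.solve(material.cell_pressure, float(p), x0=x, tol=tol,
                            max_iter=max_iter)
        if not state.converged and len(sweep.states):
            logger.warning("sweep truncated at cavity pressure %.3f MPa", p)
            break
        sweep.states.append(state)
        x = state.positions
    return sweep


def simulate_drying(mesh: CellularShellMesh, material: MaterialSpec,
                    cavity_pressure: float = 0.2,
                    dried_cell_pressure: float = 0.001,
                    tol: float = 1e-3, max_iter: int = 100_000,
                    validate: bool = True) -> tuple[StressState, StressState]:
    """Turgid vs dried wall at fixed cavity pressure.

    State A: cells at the material's turgor pressure, cavity at
    ``cavity_pressure``.  State B: cells deflated to ``dried_cell_pressure``
    (a small non-zero value keeps the compartments loaded), cavity pressure
    unchanged.  Comparing the maximum wall stress between the two states
    probes a desiccation-driven opening mechanism.
    """
    model = MembraneModel(mesh, material, validate=validate)
    inflated = model.solve(material.cell_pressure, 0.0, tol=tol,
                           max_iter=max_iter)
    state_a = model.solve(material.cell_pressure, cavity_pressure,
                          x0=inflated.positions, tol=tol, max_iter=max_iter)
    state_b = model.solve(dried_cell_pressure, cavity_pressure,
                          x0=state_a.positions, tol=tol, max_iter=max_iter)
    return state_a, state_b
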
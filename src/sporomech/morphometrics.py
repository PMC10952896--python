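"""Cell-level and organ-level shape descriptors, and torsion analysis.

Descriptors follow the conventions of comparative sporangium morphometrics:

* cell anisotropy ``2·PC1c/(PC2c + PC3c)`` from the principal components of
  each cell's geometry (1 = isotropic cell);
* cell twist ``acos|PC1c·X|`` in degrees, the angle between a cell's long
  axis and the longitudinal organ axis X = (1, 0, 0);
* sphericity, the surface area of the volume-equivalent sphere over the
  actual cavity surface area (1 for a perfect sphere);
* flatness ``(PCly + PClz)/(2·PClx)`` of the cavity geometry, where PClx is
  the extent along the longitudinal axis (> 1 for discoidal organs).

Attributes are meant to be measured on the turgid state (cells inflated at
0.5 MPa, cavity unpressurized), the state closest to the living organ; the
functions accept any vertex configuration of the same mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .fem import StressState
from .mesh import CellularShellMesh, MeshError, PrincipalAxes, principal_axes

DEG = 180.0 / np.pi


@dataclass
class SpecimenAttributes:
    """Per-sporangium scalar descriptors (the morphospace feature vector)."""

    cell_volume_mean: float    # μm³
    cell_volume_cv: float
    cell_anisotropy: float     # mean over cells
    cell_twist: float          # degrees, mean over cells
    cavity_volume: float       # μm³
    sphericity: float
    flatness: float

    def as_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def names() -> list[str]:
        return ["cell_volume_mean", "cell_volume_cv", "cell_anisotropy",
                "cell_twist", "cavity_volume", "sphericity", "flatness"]


@dataclass
class TorsionProfile:
    """Azimuthal distortion of every wall element between two states."""

    heights: np.ndarray          # element x-positions, μm (reference state)
    distortion: np.ndarray       # signed azimuthal angle change, degrees
    slope: float                 # OLS slope, degrees/μm
    intercept: float
    slope_ci99: float            # half-width of the 99% CI of the slope
    cell_tilt_change: np.ndarray  # per-cell signed tilt change, degrees
    mean_tilt_change: float

    def prediction_band(self, x: np.ndarray, level: float = 0.99):
        """Mean-prediction band of the regression line at positions ``x``."""
        n = len(self.heights)
        xm = self.heights.mean()
        sxx = np.sum((self.heights - xm) ** 2)
        resid = self.distortion - (self.slope * self.heights + self.intercept)
        s2 = np.sum(resid ** 2) / (n - 2)
        t = stats.t.ppf(0.5 + level / 2, n - 2)
        half = t * np.sqrt(s2 * (1.0 / n + (x - xm) ** 2 / sxx))
        mid = self.slope * x + self.intercept
        return mid - half, mid + half


# --------------------------------------------------------------- cell measures
def cell_anisotropy(axes: PrincipalAxes) -> float:
    """``2·PC1/(PC2 + PC3)``; 1 for an isotropic cell."""
    pc1, pc2, pc3 = axes.extents
    if pc2 + pc3 <= 0:
        raise MeshError("degenerate cell: PC2 + PC3 is zero")
    return 2.0 * pc1 / (pc2 + pc3)


def cell_twist(axes: PrincipalAxes,
               longitudinal_axis=(1.0, 0.0, 0.0)) -> float:
    """Angle (degrees, in [0, 90]) between the cell long axis and the organ axis."""
    x = np.asarray(longitudinal_axis, float)
    x = x / np.linalg.norm(x)
    d = abs(float(np.dot(axes.axes[0], x)))
    return float(np.arccos(np.clip(d, 0.0, 1.0)) * DEG)


def sphericity(cavity_volume: float, cavity_area: float) -> float:
    """Area of the volume-equivalent sphere over the actual cavity area."""
    if cavity_volume <= 0 or cavity_area <= 0:
        raise MeshError("sphericity needs positive volume and area")
    a_sphere = np.pi ** (1.0 / 3.0) * (6.0 * cavity_volume) ** (2.0 / 3.0)
    return float(a_sphere / cavity_area)


def flatness(cavity_axes: PrincipalAxes,
             longitudinal_axis=(1.0, 0.0, 0.0)) -> float:
    """``(PCly + PClz)/(2·PClx)`` with PClx the extent along the organ axis."""
    x = np.asarray(longitudinal_axis, float)
    x = x / np.linalg.norm(x)
    # reconstruct the covariance, take the variance along the organ axis and
    # the two principal variances of the transverse projection — this makes
    # the measure invariant under rotations about the organ axis
    cov = cavity_axes.axes.T @ np.diag(cavity_axes.extents ** 2) \
        @ cavity_axes.axes
    pcl_x = np.sqrt(x @ cov @ x)
    t1 = np.array([0.0, 1.0, 0.0]) if abs(x[0]) > 0.9 \
        else np.cross(x, np.array([1.0, 0.0, 0.0]))
    t1 = t1 - np.dot(t1, x) * x
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(x, t1)
    T = np.column_stack([t1, t2])
    lam = np.linalg.eigvalsh(T.T @ cov @ T)
    pcl_y, pcl_z = np.sqrt(np.maximum(lam, 0.0))
    if pcl_x <= 0:
        raise MeshError("degenerate cavity (zero longitudinal extent)")
    return float((pcl_y + pcl_z) / (2.0 * pcl_x))


# ----------------------------------------------------------------- aggregation
def cell_principal_axes(mesh: CellularShellMesh, cell: int,
                        vertices: np.ndarray | None = None) -> PrincipalAxes:
    """Principal axes of one cell compartment (area-weighted face centroids)."""
    fi, _ = mesh.compartment_faces(cell)
    cent = mesh.face_centroids(vertices)[fi]
    w = mesh.face_areas(vertices)[fi]
    return principal_axes(cent, weights=w)


def cavity_principal_axes(mesh: CellularShellMesh,
                          vertices: np.ndarray | None = None) -> PrincipalAxes:
    m = mesh.cavity_face_mask
    cent = mesh.face_centroids(vertices)[m]
    w = mesh.face_areas(vertices)[m]
    return principal_axes(cent, weights=w)


def specimen_attributes(mesh: CellularShellMesh,
                        state: StressState | None = None
                        ) -> SpecimenAttributes:
    """All seven descriptors of one specimen.

    If ``state`` is given (normally the converged cell-inflation state at
    0.5 MPa), measurements use the deformed geometry; otherwise the mesh's
    reference geometry is used.
    """
    v = state.positions if state is not None else None
    vols = mesh.cell_volumes(v)
    if len(vols) == 0:
        raise MeshError("mesh has no cells")
    mean_v = float(vols.mean())
    cv = float(vols.std() / mean_v) if mean_v > 0 else np.nan
    aniso, twist = [], []
    for c in mesh.cells:
        axes = cell_principal_axes(mesh, int(c), v)
        aniso.append(cell_anisotropy(axes))
        twist.append(cell_twist(axes, mesh.longitudinal_axis))
    cav_v = mesh.cavity_volume(v)
    cav_a = float(mesh.face_areas(v)[mesh.cavity_face_mask].sum())
    cav_axes = cavity_principal_axes(mesh, v)
    return SpecimenAttributes(
        cell_volume_mean=mean_v,
        cell_volume_cv=cv,
        cell_anisotropy=float(np.mean(aniso)),
        cell_twist=float(np.mean(twist)),
        cavity_volume=float(cav_v),
        sphericity=sphericity(cav_v, cav_a),
        flatness=flatness(cav_axes, mesh.longitudinal_axis),
    )


# --------------------------------------------------------------------- torsion
def _azimuth(points: np.ndarray) -> np.ndarray:
    return np.arctan2(points[:, 2], points[:, 1])


def torsion_analysis(reference: np.ndarray | StressState,
                     deformed: np.ndarray | StressState,
                     mesh: CellularShellMesh) -> TorsionProfile:
    """Height-resolved azimuthal distortion between two states of one mesh.

    For every non-membrane element the signed angle change about the
    longitudinal +X axis (positive = anticlockwise viewed from +X) is
    regressed on the element height; a non-zero slope means torsion
    accumulating along the organ, a uniform offset means rigid rotation.
    Per-cell tilt change is the signed rotation of each cell's long axis.
    """
    ref = reference.positions if isinstance(reference, StressState) else reference
    def_ = deformed.positions if isinstance(deformed, StressState) else deformed
    ref = np.asarray(ref, float)
    def_ = np.asarray(def_, float)
    if ref.shape != def_.shape or len(ref) != mesh.n_vertices:
        raise MeshError("states do not match the mesh")
    keep = ~mesh.is_membrane
    c_ref = mesh.face_centroids(ref)[keep]
    c_def = mesh.face_centroids(def_)[keep]
    dphi = _azimuth(c_def) - _azimuth(c_ref)
    dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
    heights = c_ref[:, 0]
    distortion = dphi * DEG

    res = stats.linregress(heights, distortion)
    n = len(heights)
    t99 = stats.t.ppf(0.995, n - 2)

    tilt_changes = []
    xhat = mesh.longitudinal_axis / np.linalg.norm(mesh.longitudinal_axis)
    for c in mesh.cells:
        a = cell_principal_axes(mesh, int(c), ref).axes[0]
        b = cell_principal_axes(mesh, int(c), def_).axes[0]
        if np.dot(a, b) < 0:
            b = -b
        s = float(np.dot(np.cross(a, b), xhat))
        ang = float(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)) * DEG)
        tilt_changes.append(np.sign(s) * ang if s != 0 else ang)
    tilt_changes = np.asarray(tilt_changes)

    return TorsionProfile(
        heights=heights, distortion=distortion,
        slope=float(res.slope), intercept=float(res.intercept),
        slope_ci99=float(t99 * res.stderr),
        cell_tilt_change=tilt_changes,
        mean_tilt_change=float(tilt_changes.mean()))
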
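"""Parametric generation of cellularized sporangium shells.

Fossil sporangia of the earliest land floras fall into a few recurring
morphotypes: near-spherical capsules, fusiform (spindle-shaped) capsules,
flat discoidal (cooksonioid) capsules, and capsules with helically twisted
cell files whose long axes run 30–40° off the organ axis.  This module
builds synthetic stand-ins for such reconstructions: an outer surface is
lofted as a generalized surface of revolution (a cross-section contour
scaled by a radius profile along the longitudinal +X axis), a rows×columns
grid of epidermal cells is painted onto it in (arc-length, azimuth)
parameter space — optionally sheared into tilted files and constrained to
the fourfold symmetry seen in these fossils — and the labeled surface is
smoothed, quality-repaired and extruded inward into watertight cell
compartments, with a basal membrane closing the sporangial cavity.

All randomness (cell-size jitter) is driven by the spec's ``rng_seed``;
rebuilding with the same spec is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .conditioning import (
    extrude_cells,
    repair_triangle_quality,
    smooth_cell_boundaries,
)
from .mesh import (
    NO_CELL,
    SIDE_INNER,
    SIDE_MEMBRANE,
    SIDE_OUTER,
    CellularShellMesh,
    MeshError,
)

MORPHOTYPES = ("spherical", "fusiform", "discoidal", "twisted", "cylindrical")

_POLE_TOL = 1e-9


@dataclass
class MorphotypeSpec:
    """Parameters of one synthetic specimen.

    ``height`` is the extent along the longitudinal +X axis, ``width`` the
    equatorial diameter (μm); ``flattening`` scales the z half-width of the
    elliptical cross-section relative to y.  ``file_tilt`` (degrees) shears
    the cell files so their long axes make that angle with the organ axis.
    ``base_opening`` is the fraction of the height truncated at the base to
    leave the attachment opening (0 closes the base with a pole).
    """

    morphotype: str = "spherical"
    height: float = 300.0
    width: float = 300.0
    flattening: float = 1.0
    cell_rows: int = 6
    cell_cols: int = 12
    file_tilt: float = 0.0
    wall_depth: float = 8.0
    fourfold_symmetry: bool = True
    jitter_sigma: float = 0.15
    rng_seed: int = 0
    n_theta: int = 32
    base_opening: float = 0.12

    def __post_init__(self) -> None:
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {self.morphotype!r}")
        if self.height <= 0 or self.width <= 0 or self.flattening <= 0:
            raise ValueError("height, width and flattening must be positive")
        if not 0 <= self.file_tilt < 90:
            raise ValueError("file_tilt must be in [0, 90) degrees")
        if self.cell_rows < 2 or self.cell_cols < 2:
            raise ValueError("cell grid needs at least 2 rows and 2 columns")
        if self.fourfold_symmetry and self.cell_cols % 4:
            raise ValueError("fourfold symmetry requires cell_cols divisible by 4")
        if not 0 <= self.base_opening < 0.5:
            raise ValueError("base_opening must be in [0, 0.5)")


def preset(morphotype: str, rng_seed: int = 0, **overrides) -> MorphotypeSpec:
    """Default specimen parameters for each fossil morphotype.

    Sizes are sub-millimetre, matching the scale of the charcoalified
    capsules these shells emulate; the twisted preset uses elongated cells
    in files tilted 35° off the axis, the discoidal preset an oblate lens
    with noisier cell sizes (cooksonioid cell-size heterogeneity).
    """
    base = {
        "spherical": dict(height=300, width=300, cell_rows=16, cell_cols=40),
        "fusiform": dict(height=450, width=180, cell_rows=14, cell_cols=16),
        "discoidal": dict(height=140, width=320, cell_rows=12, cell_cols=36,
                          jitter_sigma=0.25),
        "twisted": dict(height=400, width=150, cell_rows=6, cell_cols=20,
                        file_tilt=35.0),
        "cylindrical": dict(height=400, width=200, cell_rows=6, cell_cols=12,
                            base_opening=0.0),
    }[morphotype]
    base.update(overrides)
    return MorphotypeSpec(morphotype=morphotype, rng_seed=rng_seed, **base)


# --------------------------------------------------------------------- contours
def grid_bounds(spec: MorphotypeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Jittered cell-grid boundaries in parameter space.

    Returns ``(row_bounds, col_bounds)``: row boundaries in normalized
    profile arc length [0, 1] and column boundaries in azimuth [0, 2π].
    Widths carry multiplicative lognormal jitter (σ = ``jitter_sigma``,
    seeded by ``rng_seed``); with fourfold symmetry one quadrant's column
    pattern is tiled four times.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols, sig = spec.cell_rows, spec.cell_cols, spec.jitter_sigma
    row_w = rng.lognormal(0.0, sig, rows) if sig > 0 else np.ones(rows)
    if spec.fourfold_symmetry:
        quad = rng.lognormal(0.0, sig, cols // 4) if sig > 0 \
            else np.ones(cols // 4)
        col_w = np.tile(quad, 4)
    else:
        col_w = rng.lognormal(0.0, sig, cols) if sig > 0 else np.ones(cols)
    row_bounds = np.concatenate([[0.0], np.cumsum(row_w)]) / row_w.sum()
    col_bounds = np.concatenate([[0.0], np.cumsum(col_w)]) \
        / col_w.sum() * 2 * np.pi
    return row_bounds, col_bounds


def cross_section_contour(spec: MorphotypeSpec) -> np.ndarray:
    """Elliptical cross-section polyline, CCW in the (y, z) plane.

    Sampling angles follow the specimen's jittered column boundaries, each
    column subdivided so the total point count is close to ``n_theta``;
    cell boundaries therefore coincide with mesh vertex columns.
    """
    _, col_bounds = grid_bounds(spec)
    target = 2 * np.pi / spec.n_theta
    phi = []
    for a, b in zip(col_bounds[:-1], col_bounds[1:]):
        nsub = max(1, int(round((b - a) / target)))
        phi.append(np.linspace(a, b, nsub, endpoint=False))
    phi = np.concatenate(phi)
    return np.column_stack([np.cos(phi), spec.flattening * np.sin(phi)])


def profile_curve(spec: MorphotypeSpec, n: int = 241) -> np.ndarray:
    """Radius-vs-height polyline (x, r) along the longitudinal axis."""
    H, R = spec.height, spec.width / 2.0
    x0 = spec.base_opening * H
    x = np.linspace(x0, H, n)
    if spec.morphotype in ("spherical", "discoidal", "fusiform", "twisted"):
        # ellipse of revolution: oblate (discoidal), spherical, or prolate
        # spindle (fusiform/twisted); tip curvature radius (width/2)²/(H/2)
        # stays well above the 8 μm wall depth for all presets
        u = np.clip((x - H / 2) / (H / 2), -1.0, 1.0)
        r = R * np.sqrt(np.maximum(1.0 - u * u, 0.0))
    elif spec.morphotype == "cylindrical":
        r = np.full_like(x, R)
    else:  # pragma: no cover
        raise ValueError(spec.morphotype)
    return np.column_stack([x, r])


# ------------------------------------------------------------------------ loft
def loft_surface(cross_section: np.ndarray, profile: np.ndarray,
                 n_rows: int | None = None,
                 s_positions: np.ndarray | None = None,
                 ring_offsets: np.ndarray | None = None) -> CellularShellMesh:
    """Surface of generalized revolution from a cross-section and a profile.

    At each height along the profile the closed 2-D ``cross_section``
    contour is scaled by the local profile radius.  By default, ring
    spacing follows the profile arc length and is matched to the mean
    azimuthal spacing so the quadrilateral faces are close to square before
    triangulation; explicit ring placement (``s_positions``, absolute arc
    lengths along the profile including both endpoints) overrides this.
    ``ring_offsets`` rotates each ring's contour about the axis (radians) —
    used to build helically sheared cell files.  A pole vertex with a
    triangle fan is used wherever the profile radius vanishes at an end.
    The result is an outward-oriented, outer-side-only mesh (all faces
    provisionally in cell 0).
    """
    cs = np.asarray(cross_section, float)
    prof = np.asarray(profile, float)
    if len(cs) < 3:
        raise MeshError("cross-section needs at least 3 points")
    # enforce CCW contour
    area2 = np.sum(cs[:, 0] * np.roll(cs[:, 1], -1)
                   - np.roll(cs[:, 0], -1) * cs[:, 1])
    if area2 < 0:
        cs = cs[::-1]
    x_p, r_p = prof[:, 0], prof[:, 1]
    if np.any(r_p[1:-1] <= 0):
        raise MeshError("profile radius must be positive at interior heights")
    seg = np.hypot(np.diff(x_p), np.diff(r_p))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    L = arc[-1]
    if L <= 0:
        raise MeshError("degenerate profile")
    M = len(cs)
    perim_unit = np.sum(np.linalg.norm(np.diff(
        np.vstack([cs, cs[:1]]), axis=0), axis=1))
    r_mean = np.trapezoid(r_p, arc) / L
    if s_positions is not None:
        s = np.asarray(s_positions, float)
        if s[0] != 0 or abs(s[-1] - L) > 1e-9 * max(L, 1.0) \
                or np.any(np.diff(s) <= 0):
            raise MeshError("s_positions must increase from 0 to the "
                            "profile arc length")
        n_rows = len(s) - 1
    else:
        if n_rows is None:
            n_rows = max(3, int(round(L * M / max(perim_unit * r_mean, 1e-12))))
        s = np.linspace(0.0, L, n_rows + 1)
    if ring_offsets is None:
        offs = np.zeros(n_rows + 1)
    else:
        offs = np.asarray(ring_offsets, float)
        if len(offs) != n_rows + 1:
            raise MeshError("ring_offsets must have one entry per ring")
    x_s = np.interp(s, arc, x_p)
    r_s = np.interp(s, arc, r_p)

    base_pole = r_s[0] < _POLE_TOL
    apex_pole = r_s[-1] < _POLE_TOL
    ring_rows = np.arange(n_rows + 1)[
        (r_s >= _POLE_TOL)]
    verts = []
    ring_offset = {}
    for i in ring_rows:
        ring_offset[i] = len(verts) * 1
        c, sn = np.cos(offs[i]), np.sin(offs[i])
        for j in range(M):
            y = r_s[i] * cs[j, 0]
            z = r_s[i] * cs[j, 1]
            verts.append([x_s[i], c * y - sn * z, sn * y + c * z])
    verts = np.array(verts, float).reshape(-1, 3)
    faces = []
    rows_list = list(ring_rows)
    for a, b in zip(rows_list[:-1], rows_list[1:]):
        oa, ob = ring_offset[a], ring_offset[b]
        for j in range(M):
            k = (j + 1) % M
            # alternate the quad diagonal in a checkerboard: a uniform
            # diagonal direction would make the discrete shell chiral and
            # induce a spurious twist under pressure
            if (a + j) % 2 == 0:
                faces.append([oa + j, oa + k, ob + k])
                faces.append([oa + j, ob + k, ob + j])
            else:
                faces.append([oa + j, oa + k, ob + j])
                faces.append([oa + k, ob + k, ob + j])
    all_v = [verts]
    if base_pole:
        pole = np.array([[x_s[0], 0.0, 0.0]])
        pi = len(verts)
        all_v.append(pole)
        o = ring_offset[rows_list[0]]
        for j in range(M):
            k = (j + 1) % M
            faces.append([o + k, o + j, pi])
    if apex_pole:
        pole = np.array([[x_s[-1], 0.0, 0.0]])
        pi = sum(len(v) for v in all_v)
        all_v.append(pole)
        o = ring_offset[rows_list[-1]]
        for j in range(M):
            k = (j + 1) % M
            faces.append([o + j, o + k, pi])
    vertices = np.vstack(all_v)
    faces = np.asarray(faces, np.int64)
    return CellularShellMesh(
        vertices=vertices, faces=faces,
        cell_id=np.zeros(len(faces), np.int64),
        side=np.full(len(faces), SIDE_OUTER, np.int64))


# ------------------------------------------------------------------ tessellate
def _shear_table(spec: MorphotypeSpec):
    """Cumulative azimuthal shear of the cell files along the meridian.

    Integrates dtheta/ds = tan(tilt)/r so the files make a constant angle
    with the meridian; the radius is floored near the poles to keep the
    integral finite.  Returns (profile x, arc-length grid, shear angles).
    """
    prof = profile_curve(spec)
    x_p, r_p = prof[:, 0], prof[:, 1]
    seg = np.hypot(np.diff(x_p), np.diff(r_p))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    L = arc[-1]
    r_mean = np.trapezoid(r_p, arc) / L
    tilt = np.deg2rad(spec.file_tilt)
    r_eff = np.maximum(r_p, 0.25 * r_mean)
    dtheta = np.tan(tilt) / r_eff
    shear = np.concatenate([[0.0], np.cumsum(
        0.5 * (dtheta[1:] + dtheta[:-1]) * seg)])
    return x_p, arc, shear


def tessellate_cells(surface: CellularShellMesh,
                     spec: MorphotypeSpec) -> CellularShellMesh:
    """Assign faces of a lofted surface to a rows-by-cols grid of cells.

    The grid lives in (normalized profile arc length, azimuth) space, with
    jittered boundaries from :func:`grid_bounds`; a positive ``file_tilt``
    shears the column boundaries with height so cell long axes make that
    angle with the longitudinal axis (anticlockwise about +X for positive
    tilt).  Faces are assigned by centroid; on grids built by
    :func:`build_specimen` the cell boundaries coincide with mesh edges, so
    the assignment is exact.
    """
    row_bounds, col_bounds = grid_bounds(spec)
    rows, cols = spec.cell_rows, spec.cell_cols
    x_p, arc, shear = _shear_table(spec)
    L = arc[-1]

    cent = surface.face_centroids()
    s_f = np.interp(cent[:, 0], x_p, arc) / L
    theta = np.arctan2(cent[:, 2], cent[:, 1])
    shear_f = np.interp(s_f * L, arc, shear)
    theta_p = np.mod(theta - shear_f, 2 * np.pi)
    row = np.clip(np.searchsorted(row_bounds[1:-1], s_f, side="right"),
                  0, rows - 1)
    col = np.clip(np.searchsorted(col_bounds[1:-1], theta_p, side="right"),
                  0, cols - 1)
    out = surface.copy()
    out.cell_id = (row * cols + col).astype(np.int64)
    return out


# -------------------------------------------------------------------- membrane
def close_cavity(mesh: CellularShellMesh) -> CellularShellMesh:
    """Close open rims of the inner surface with membrane fans.

    Each boundary loop of the inner (cavity) surface is filled with a
    triangle fan around its centroid; the new faces are labeled
    ``membrane`` (load-bearing, excluded from stress statistics) and carry
    no cell.  Orientation is inherited from the inner surface so the cavity
    boundary stays a consistently outward-oriented closed surface.
    """
    inner = mesh.faces[mesh.side == SIDE_INNER]
    if len(inner) == 0:
        raise MeshError("mesh has no inner faces")
    e = np.concatenate([inner[:, [0, 1]], inner[:, [1, 2]], inner[:, [2, 0]]])
    key = np.sort(e, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    bnd = e[counts[inv] == 1]
    if len(bnd) == 0:
        return mesh
    nxt = {int(u): int(w) for u, w in bnd}
    loops = []
    seen = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(loop)
    v = mesh.vertices
    new_v = [v]
    new_f, nv = [], len(v)
    for loop in loops:
        center = v[loop].mean(axis=0)
        ci = nv
        new_v.append(center[None])
        nv += 1
        for a, b in zip(loop, loop[1:] + loop[:1]):
            # inner faces traverse a->b; the membrane takes b->a
            new_f.append([ci, b, a])
    n_new = len(new_f)
    return CellularShellMesh(
        vertices=np.vstack(new_v),
        faces=np.vstack([mesh.faces, np.asarray(new_f, np.int64)]),
        cell_id=np.concatenate([mesh.cell_id,
                                np.full(n_new, NO_CELL, np.int64)]),
        side=np.concatenate([mesh.side,
                             np.full(n_new, SIDE_MEMBRANE, np.int64)]),
        cell_id2=np.concatenate([mesh.cell_id2,
                                 np.full(n_new, NO_CELL, np.int64)]),
        longitudinal_axis=mesh.longitudinal_axis.copy())


# ---------------------------------------------------------------------- driver
def build_specimen(spec: MorphotypeSpec) -> CellularShellMesh:
    """Full construction pipeline for one synthetic specimen.

    Loft -> tessellate -> boundary smoothing (3 passes) -> triangle-quality
    repair (aspect > 2, 3 passes) -> inward extrusion by ``wall_depth`` ->
    basal membrane.  The loft is built on the specimen's own (jittered,
    sheared) cell grid: rings are placed at the cell row boundaries and the
    contour is sampled at the cell column boundaries, each subdivided to
    near-square faces, with per-ring azimuthal offsets following the file
    shear.  Cell boundaries therefore coincide with mesh edges — the mesh
    follows the cell files, as in surface reconstructions of real epidermal
    tissue.  Deterministic for a given spec (including its seed).
    """
    cs = cross_section_contour(spec)
    prof = profile_curve(spec)
    x_p, r_p = prof[:, 0], prof[:, 1]
    seg = np.hypot(np.diff(x_p), np.diff(r_p))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    L = arc[-1]
    perim = np.sum(np.linalg.norm(np.diff(np.vstack([cs, cs[:1]]), axis=0),
                                  axis=1))
    r_mean = np.trapezoid(r_p, arc) / L
    ds_target = perim * r_mean / len(cs)
    # rings subdivide each cell row to near-square spacing
    row_bounds, _ = grid_bounds(spec)
    s_pos = [0.0]
    for a, b in zip(row_bounds[:-1], row_bounds[1:]):
        span = (b - a) * L
        nsub = max(1, int(round(span / max(ds_target, 1e-12))))
        s_pos.extend(a * L + span * np.arange(1, nsub + 1) / nsub)
    s_pos = np.asarray(s_pos)
    s_pos[-1] = L
    _, arc_t, shear = _shear_table(spec)
    ring_offsets = np.interp(s_pos, arc_t, shear)
    surf = loft_surface(cs, prof, s_positions=s_pos,
                        ring_offsets=ring_offsets)
    surf = tessellate_cells(surf, spec)
    surf = smooth_cell_boundaries(surf, passes=3)
    surf = repair_triangle_quality(surf, max_aspect=2.0, passes=3)
    mesh = extrude_cells(surf, depth=spec.wall_depth)
    mesh = close_cavity(mesh)
    mesh.validate()
    return mesh


# ------------------------------------------------------------------ benchmarks
def icosphere_shell(radius: float, subdivisions: int = 3) -> CellularShellMesh:
    """Closed single-compartment spherical shell (for pressure benchmarks).

    All faces are cavity-facing (``inner``) so a cavity-pressure load
    inflates the sphere; cell pressure should be zero.
    """
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    n = len(tm.faces)
    return CellularShellMesh(
        vertices=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces, np.int64),
        cell_id=np.zeros(n, np.int64),
        side=np.full(n, SIDE_INNER, np.int64))


def capsule_shell(radius: float, length: float,
                  count: tuple[int, int] = (24, 24)) -> CellularShellMesh:
    """Closed cylinder with hemispherical caps, axis +X, centered at origin.

    ``length`` is the cylindrical (tube) section length; single
    compartment, all faces cavity-facing.
    """
    tm = trimesh.creation.capsule(height=length, radius=radius, count=count)
    v = np.asarray(tm.vertices, float)
    v = v - v.mean(axis=0)
    v = v[:, [2, 1, 0]] * np.array([1.0, 1.0, -1.0])  # z-axis -> x-axis
    n = len(tm.faces)
    return CellularShellMesh(
        vertices=v,
        faces=np.asarray(tm.faces, np.int64),
        cell_id=np.zeros(n, np.int64),
        side=np.full(n, SIDE_INNER, np.int64))
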
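"""Mesh-conditioning operators applied to reconstructed sporangium surfaces.

Three operators mirror the preparation steps needed before a cellular shell
can be pressurized reliably:

* :func:`smooth_cell_boundaries` — relax vertices on the polylines where two
  epidermal cells meet, by repeated neighbour averaging.
* :func:`repair_triangle_quality` — merge high-aspect-ratio (sliver)
  triangles with a same-cell neighbour and retriangulate; slivers degrade
  the convergence of the membrane solver.
* :func:`extrude_cells` — thicken a labeled outer surface into closed
  prism-like cell compartments of a given wall depth (8 μm by default,
  the cell depth seen in fractured charcoalified material).
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .mesh import (
    NO_CELL,
    SIDE_ANTICLINAL,
    SIDE_INNER,
    SIDE_OUTER,
    CellularShellMesh,
    MeshError,
)

logger = logging.getLogger(__name__)

_SQRT3 = np.sqrt(3.0)


# --------------------------------------------------------------------- quality
def triangle_aspect_ratio(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Longest edge over twice the inradius, normalized to 1 for equilateral.

    Monotone in sliver-ness: needle and cap triangles score high, well-shaped
    triangles score near 1.
    """
    v = np.asarray(vertices, float)
    f = np.asarray(faces, np.int64).reshape(-1, 3)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    lmax = np.max([la, lb, lc], axis=0)
    s = 0.5 * (la + lb + lc)
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    inradius = area / np.maximum(s, 1e-300)
    with np.errstate(divide="ignore"):
        ar = lmax / np.maximum(2.0 * inradius, 1e-300)
    return ar / _SQRT3


# ------------------------------------------------------------------- smoothing
def _boundary_graph(mesh: CellularShellMesh):
    """Vertices on cell-cell boundaries and their boundary-vertex neighbours.

    Works on the outer-surface patchwork (all faces if no outer faces exist).
    Returns (boundary_mask, junction_mask, adjacency dict).
    """
    use = mesh.side == SIDE_OUTER
    if not use.any():
        use = np.ones(mesh.n_faces, bool)
    faces = mesh.faces[use]
    cells = mesh.cell_id[use]

    incident: dict[int, set] = defaultdict(set)
    for f, c in zip(faces, cells):
        for vi in f:
            incident[int(vi)].add(int(c))
    n_cells = np.zeros(mesh.n_vertices, dtype=int)
    for vi, cs in incident.items():
        n_cells[vi] = len(cs)
    boundary = n_cells >= 2
    junction = n_cells >= 3

    adj: dict[int, set] = defaultdict(set)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    for u, v in e:
        if boundary[u] and boundary[v]:
            adj[int(u)].add(int(v))
            adj[int(v)].add(int(u))
    # pin vertices on the free (open) boundary of the surface — e.g. the
    # basal rim — alongside junctions: moving them would distort the rim
    key = np.sort(e, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    for u, v in uniq[counts == 1]:
        junction[u] = junction[v] = True
    return boundary, junction, adj


def smooth_cell_boundaries(mesh: CellularShellMesh,
                           passes: int = 3) -> CellularShellMesh:
    """Average cell-boundary vertices with their boundary neighbours.

    Each pass performs a simultaneous (Jacobi) update: a boundary vertex
    moves toward the mean of itself and its boundary neighbours, keeping
    only the displacement component that is transverse to the local
    boundary direction *and* lies in the local surface tangent plane (so
    already-straight boundaries are fixed points, vertices neither slide
    along the boundary nor leave the wall surface, and triangle areas are
    preserved to first order).  Junction vertices where three or more cells
    meet are kept fixed; labels and topology are untouched.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    out = mesh.copy()
    if passes == 0:
        return out
    boundary, junction, adj = _boundary_graph(out)
    movable = [int(v) for v in np.where(boundary & ~junction)[0]]
    lonely = [v for v in movable if not adj.get(v)]
    if lonely:
        logger.warning("smooth_cell_boundaries: %d isolated boundary "
                       "vertices left unchanged", len(lonely))
    # incident faces per movable vertex, for the local quality safeguard
    incident_faces: dict[int, list[int]] = defaultdict(list)
    movable_set = set(movable)
    for fi, tri in enumerate(out.faces):
        for vi in tri:
            if int(vi) in movable_set:
                incident_faces[int(vi)].append(fi)

    for _ in range(passes):
        v = out.vertices.copy()
        # area-weighted vertex normals at the start of the pass
        fav = out.face_area_vectors()
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, out.faces[:, k], fav)
        vn /= np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-300)
        # sequential (Gauss-Seidel) update: each move sees its neighbours'
        # current positions, making the local quality safeguard exact
        for vi in movable:
            nbrs = [n for n in adj.get(vi, ()) if boundary[n]]
            if not nbrs:
                continue
            pts = v[nbrs]
            target = (v[vi] + pts.sum(axis=0)) / (1 + len(pts))
            d = target - v[vi]
            if len(pts) >= 2:
                t = pts[-1] - pts[0]
                nt = np.linalg.norm(t)
                if nt > 1e-300:
                    t /= nt
                    # in-surface direction transverse to the boundary
                    u = np.cross(vn[vi], t)
                    nu = np.linalg.norm(u)
                    if nu > 1e-300:
                        u /= nu
                        d = np.dot(d, u) * u
                    else:
                        d = d - np.dot(d, t) * t
            if not _move_is_safe(v, out.faces, incident_faces[vi], vi,
                                 v[vi] + d):
                continue
            v[vi] = v[vi] + d
        out.vertices = v
    return out


def _move_is_safe(v: np.ndarray, faces: np.ndarray, incident: list[int],
                  vi: int, pos: np.ndarray) -> bool:
    """Would moving vertex ``vi`` to ``pos`` degrade its incident triangles?

    Rejects moves that flip a triangle, shrink its area below 30% of the
    current value, or leave a triangle's aspect ratio above 2.5 without
    clearly improving it — in particular, thin pole wedges may only be
    touched by moves that make them better.
    """
    for fi in incident:
        tri = faces[fi]
        p = [pos if int(t) == vi else v[t] for t in tri]
        old = [v[t] for t in tri]
        n_new = np.cross(p[1] - p[0], p[2] - p[0])
        n_old = np.cross(old[1] - old[0], old[2] - old[0])
        a_new, a_old = np.linalg.norm(n_new), np.linalg.norm(n_old)
        if a_new < 0.3 * a_old or np.dot(n_new, n_old) <= 0:
            return False
        ar_new = triangle_aspect_ratio(np.asarray(p), np.array([[0, 1, 2]]))[0]
        ar_old = triangle_aspect_ratio(np.asarray(old), np.array([[0, 1, 2]]))[0]
        if ar_new > 2.5 and ar_new > 0.9 * ar_old:
            return False
    return True


# ---------------------------------------------------------------------- repair
def _face_adjacency(faces: np.ndarray):
    """Map undirected edge -> list of (face index, local edge index)."""
    edge_map: dict[tuple, list] = defaultdict(list)
    for fi, (a, b, c) in enumerate(faces):
        for k, (u, v) in enumerate(((a, b), (b, c), (c, a))):
            edge_map[(min(u, v), max(u, v))].append((fi, k))
    return edge_map


def repair_triangle_quality(mesh: CellularShellMesh, max_aspect: float = 2.0,
                            passes: int = 3) -> CellularShellMesh:
    """Merge sliver triangles with a same-cell neighbour and retriangulate.

    Each pass visits triangles whose aspect ratio exceeds ``max_aspect``
    (worst first), merges each with the same-cell, same-side neighbour
    across one of its edges into a quadrilateral, and retriangulates along
    the diagonal that minimizes the new maximum aspect ratio.  A merge is
    applied only when it strictly lowers the pairwise maximum aspect ratio
    and keeps both triangles valid, so the number of offending triangles is
    non-increasing.  Vertices never move, hence enclosed volumes change only
    through the retriangulated quads (a sub-0.5% effect on the shells used
    here).  Offenders with no admissible neighbour are skipped and logged.
    """
    out = mesh.copy()
    for _ in range(max(passes, 0)):
        faces = out.faces
        ar = triangle_aspect_ratio(out.vertices, faces)
        offenders = np.where(ar > max_aspect)[0]
        if len(offenders) == 0:
            break
        offenders = offenders[np.argsort(-ar[offenders])]
        edge_map = _face_adjacency(faces)
        face_keys = {tuple(sorted(map(int, f))) for f in faces}
        touched = np.zeros(len(faces), bool)
        n_applied = 0
        for fi in offenders:
            if touched[fi]:
                continue
            if not _try_flip(out, int(fi), ar, edge_map, touched, max_aspect,
                             face_keys):
                logger.debug("repair: no admissible merge for face %d", fi)
            else:
                n_applied += 1
        if n_applied == 0:
            break
    return out


def _try_flip(mesh: CellularShellMesh, fi: int, ar: np.ndarray,
              edge_map, touched: np.ndarray, max_aspect: float,
              face_keys: set) -> bool:
    from .conditioning import triangle_aspect_ratio as _ar  # self-import safe
    faces = mesh.faces
    v = mesh.vertices
    tri = faces[fi]
    # edges sorted longest first
    lens = [np.linalg.norm(v[tri[(k + 1) % 3]] - v[tri[k]]) for k in range(3)]
    for k in np.argsort(lens)[::-1]:
        u, w = int(tri[k]), int(tri[(k + 1) % 3])
        p = int(tri[(k + 2) % 3])
        partners = [(gj, gk) for gj, gk in edge_map[(min(u, w), max(u, w))]
                    if gj != fi]
        if not partners:
            continue
        gj, gk = partners[0]
        if touched[gj]:
            continue
        if (mesh.cell_id[gj] != mesh.cell_id[fi]
                or mesh.side[gj] != mesh.side[fi]):
            continue
        gtri = faces[gj]
        q = int(gtri[(gk + 2) % 3])
        if q in (u, w, p):
            continue
        # flip diagonal (u,w) -> (p,q); orientation preserved
        new1 = np.array([p, u, q])
        new2 = np.array([p, q, w])
        a1 = np.cross(v[new1[1]] - v[new1[0]], v[new1[2]] - v[new1[0]])
        a2 = np.cross(v[new2[1]] - v[new2[0]], v[new2[2]] - v[new2[0]])
        old = np.cross(v[tri[1]] - v[tri[0]], v[tri[2]] - v[tri[0]])
        if (np.linalg.norm(a1) < 1e-12 or np.linalg.norm(a2) < 1e-12
                or np.dot(a1, old) <= 0 or np.dot(a2, old) <= 0):
            continue
        new_ar = _ar(v, np.array([new1, new2]))
        old_max = max(ar[fi], ar[gj])
        old_off = int(ar[fi] > max_aspect) + int(ar[gj] > max_aspect)
        new_off = int((new_ar > max_aspect).sum())
        # the pair's worst aspect ratio must never degrade; within that,
        # accept either a strict improvement of the worst or a reduction in
        # the number of offenders
        improves_worst = new_ar.max() < old_max - 1e-12
        improves_count = new_off < old_off and new_ar.max() <= old_max + 1e-12
        if not (improves_worst or improves_count):
            continue
        # the retriangulation must not duplicate a triangle that already
        # exists elsewhere (possible in heavily degenerate sliver clusters)
        k1 = tuple(sorted(map(int, new1)))
        k2 = tuple(sorted(map(int, new2)))
        if k1 in face_keys or k2 in face_keys or k1 == k2:
            continue
        face_keys.discard(tuple(sorted(map(int, tri))))
        face_keys.discard(tuple(sorted(map(int, gtri))))
        face_keys.add(k1)
        face_keys.add(k2)
        faces[fi] = new1
        faces[gj] = new2
        touched[fi] = touched[gj] = True
        return True
    return False


# --------------------------------------------------------------------- extrude
def extrude_cells(surface: CellularShellMesh, depth: float = 8.0
                  ) -> CellularShellMesh:
    """Thicken a labeled outer surface into closed cell compartments.

    The outer faces are kept; each vertex is offset inward by ``depth``
    along its area-weighted normal to create the inner (cavity) surface;
    anticlinal walls are inserted along cell-cell boundary edges and along
    open rim edges, making each cell's wall compartment watertight.

    Raises :class:`MeshError` for non-positive depth and when the inward
    offset would fold the inner surface (depth too large for the local
    curvature), naming an affected cell.
    """
    if depth <= 0:
        raise MeshError("extrusion depth must be positive")
    if np.any(surface.side != SIDE_OUTER):
        raise MeshError("extrude_cells expects an outer-only surface")
    v = surface.vertices
    faces = surface.faces
    nV = len(v)

    # area-weighted vertex normals (outward)
    fav = surface.face_area_vectors()
    vn = np.zeros_like(v)
    for k in range(3):
        np.add.at(vn, faces[:, k], fav)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    vn = vn / np.maximum(norms, 1e-300)

    inner_v = v - depth * vn
    all_v = np.vstack([v, inner_v])

    inner_faces = faces + nV
    # fold check: inner face normals must agree with outer
    ib, ic = all_v[inner_faces[:, 1]], all_v[inner_faces[:, 2]]
    ia = all_v[inner_faces[:, 0]]
    inner_av = 0.5 * np.cross(ib - ia, ic - ia)
    bad = np.einsum("ij,ij->i", inner_av, fav) <= 0
    # offsets past the local centre of curvature keep face orientation but
    # turn a closed shell inside out: the inner surface must stay
    # star-shaped about its own centroid (outward normals point away from
    # it).  Only meaningful for closed outer surfaces.
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    _, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
    if not np.any(counts == 1):          # closed surface
        centroid = inner_v.mean(axis=0)
        inner_cent = (ia + ib + ic) / 3.0
        bad |= np.einsum("ij,ij->i", inner_av, inner_cent - centroid) <= 0
    if bad.any():
        cell = int(surface.cell_id[np.where(bad)[0][0]])
        raise MeshError(f"inward offset folds the inner surface of cell "
                        f"{cell}; reduce depth")

    new_faces = [faces, inner_faces]
    new_cell = [surface.cell_id, surface.cell_id.copy()]
    new_cell2 = [np.full(len(faces), NO_CELL, np.int64)] * 2
    new_side = [np.full(len(faces), SIDE_OUTER, np.int64),
                np.full(len(faces), SIDE_INNER, np.int64)]

    wall_f, wall_c, wall_c2 = [], [], []

    edge_map = _face_adjacency(faces)
    for (_, _), uses in edge_map.items():
        if len(uses) > 2:
            raise MeshError("non-manifold edge in outer surface")
        f1, k1 = uses[0]
        tri = faces[f1]
        u, w = int(tri[k1]), int(tri[(k1 + 1) % 3])   # directed edge of f1
        c1 = int(surface.cell_id[f1])
        if len(uses) == 2:
            c2 = int(surface.cell_id[uses[1][0]])
            if c1 == c2:
                continue
            # interior wall between c1 and c2; faces built from f1's directed
            # edge point toward c1, so the owner (normal source) is c2
            wall_f.append([u, w, w + nV]); wall_f.append([u, w + nV, u + nV])
            wall_c += [c2, c2]
            wall_c2 += [c1, c1]
        else:
            # rim wall facing the exterior: normal away from c1
            wall_f.append([w, u, u + nV]); wall_f.append([w, u + nV, w + nV])
            wall_c += [c1, c1]
            wall_c2 += [NO_CELL, NO_CELL]

    if wall_f:
        new_faces.append(np.asarray(wall_f, np.int64))
        new_cell.append(np.asarray(wall_c, np.int64))
        new_cell2.append(np.asarray(wall_c2, np.int64))
        new_side.append(np.full(len(wall_f), SIDE_ANTICLINAL, np.int64))

    out = CellularShellMesh(
        vertices=all_v,
        faces=np.vstack(new_faces),
        cell_id=np.concatenate(new_cell),
        side=np.concatenate(new_side),
        cell_id2=np.concatenate(new_cell2),
        longitudinal_axis=surface.longitudinal_axis.copy(),
    )
    return out
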
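"""Cellularized shell meshes and geometric measures.

The central container is :class:`CellularShellMesh`: a triangle mesh whose
faces are labeled by the epidermal cell they belong to and by which surface
of the wall they lie on.  A sporangium wall is modeled as a single layer of
closed, prism-like cell compartments sandwiched between an outer and an
inner (cavity-facing) surface, connected by anticlinal side walls; a basal
membrane closes the sporangial cavity at the attachment opening.

Units: lengths in micrometres (μm), areas μm², volumes μm³.

Orientation conventions (load and volume bookkeeping rely on them):

* ``outer`` faces: normals point away from the organ.
* ``inner`` and ``membrane`` faces: normals point out of the cavity
  (into the wall / substrate), so the cavity boundary is an
  outward-oriented closed surface.
* ``anticlinal`` faces: normals point from the owning cell (``cell_id``)
  toward the neighbouring cell (``cell_id2``; −1 when the wall faces the
  exterior, e.g. at the basal rim).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

# face side labels
SIDE_OUTER = 0
SIDE_INNER = 1
SIDE_ANTICLINAL = 2
SIDE_MEMBRANE = 3

SIDE_NAMES = {
    SIDE_OUTER: "outer",
    SIDE_INNER: "inner",
    SIDE_ANTICLINAL: "anticlinal",
    SIDE_MEMBRANE: "membrane",
}

#: label used for the basal membrane (no cell)
NO_CELL = -1

_DUPLICATE_TOL = 1e-9


class MeshError(ValueError):
    """Raised when a mesh violates a structural precondition."""


@dataclass
class PrincipalAxes:
    """Principal directions and standard-deviation extents of a point set.

    ``axes[i]`` is the unit eigenvector of the point covariance belonging to
    ``extents[i]``; extents are square roots of the covariance eigenvalues
    (length-like), sorted descending.
    """

    axes: np.ndarray      # (3, 3), rows are unit vectors
    extents: np.ndarray   # (3,), μm, descending

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        self.extents = np.asarray(self.extents, dtype=float)


@dataclass
class CellularShellMesh:
    """Triangle mesh with per-face cell and wall-side labels."""

    vertices: np.ndarray            # (V, 3) float, μm
    faces: np.ndarray               # (F, 3) int
    cell_id: np.ndarray             # (F,) int, −1 for membrane
    side: np.ndarray                # (F,) int, see SIDE_* constants
    cell_id2: np.ndarray | None = None  # (F,) int, neighbour across anticlinal walls
    longitudinal_axis: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.cell_id = np.asarray(self.cell_id, dtype=np.int64)
        self.side = np.asarray(self.side, dtype=np.int64)
        if self.cell_id2 is None:
            self.cell_id2 = np.full(len(self.faces), NO_CELL, dtype=np.int64)
        else:
            self.cell_id2 = np.asarray(self.cell_id2, dtype=np.int64)
        self.longitudinal_axis = np.asarray(self.longitudinal_axis, dtype=float)

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "CellularShellMesh":
        return CellularShellMesh(
            self.vertices.copy(), self.faces.copy(), self.cell_id.copy(),
            self.side.copy(), self.cell_id2.copy(),
            self.longitudinal_axis.copy())

    def with_vertices(self, vertices: np.ndarray) -> "CellularShellMesh":
        """Same labels/topology on new vertex positions (e.g. a deformed state)."""
        return replace(self, vertices=np.asarray(vertices, dtype=float))

    # --------------------------------------------------------------- geometry
    def triangle_corners(self, vertices: np.ndarray | None = None):
        v = self.vertices if vertices is None else vertices
        return v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]

    def face_area_vectors(self, vertices: np.ndarray | None = None) -> np.ndarray:
        a, b, c = self.triangle_corners(vertices)
        return 0.5 * np.cross(b - a, c - a)

    def face_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        return np.linalg.norm(self.face_area_vectors(vertices), axis=1)

    def face_normals(self, vertices: np.ndarray | None = None) -> np.ndarray:
        av = self.face_area_vectors(vertices)
        n = np.linalg.norm(av, axis=1, keepdims=True)
        return av / np.maximum(n, 1e-300)

    def face_centroids(self, vertices: np.ndarray | None = None) -> np.ndarray:
        a, b, c = self.triangle_corners(vertices)
        return (a + b + c) / 3.0

    # ----------------------------------------------------------------- labels
    @property
    def cells(self) -> np.ndarray:
        ids = np.unique(self.cell_id)
        return ids[ids >= 0]

    @property
    def is_membrane(self) -> np.ndarray:
        return self.side == SIDE_MEMBRANE

    @property
    def cavity_face_mask(self) -> np.ndarray:
        return (self.side == SIDE_INNER) | (self.side == SIDE_MEMBRANE)

    def compartment_faces(self, cell: int):
        """Faces bounding cell ``cell`` with outward-from-compartment signs.

        Returns ``(face_indices, signs)``; the signed faces form an
        outward-oriented closed surface of that cell's wall compartment.
        """
        owner = self.cell_id == cell
        signs = []
        idx = []
        f_outer = np.where(owner & (self.side == SIDE_OUTER))[0]
        idx.append(f_outer); signs.append(np.ones(len(f_outer)))
        f_inner = np.where(owner & (self.side == SIDE_INNER))[0]
        idx.append(f_inner); signs.append(-np.ones(len(f_inner)))
        f_wall = np.where(owner & (self.side == SIDE_ANTICLINAL))[0]
        idx.append(f_wall); signs.append(np.ones(len(f_wall)))
        f_nbr = np.where((self.cell_id2 == cell) & (self.side == SIDE_ANTICLINAL))[0]
        idx.append(f_nbr); signs.append(-np.ones(len(f_nbr)))
        return np.concatenate(idx).astype(np.int64), np.concatenate(signs)

    # ---------------------------------------------------------------- volumes
    def cavity_volume(self, vertices: np.ndarray | None = None) -> float:
        """Volume enclosed by the cavity boundary (inner + membrane faces)."""
        m = self.cavity_face_mask
        v = self.vertices if vertices is None else vertices
        return enclosed_volume(v, self.faces[m])

    def cell_volumes(self, vertices: np.ndarray | None = None) -> np.ndarray:
        """Watertight volume of every cell compartment, ordered by cell id."""
        v = self.vertices if vertices is None else vertices
        a = v[self.faces[:, 0]]
        det = np.einsum("ij,ij->i", a, np.cross(v[self.faces[:, 1]],
                                                v[self.faces[:, 2]]))
        vols = np.empty(len(self.cells))
        for k, c in enumerate(self.cells):
            fi, s = self.compartment_faces(int(c))
            vols[k] = abs(np.sum(s * det[fi]) / 6.0)
        return vols

    # ------------------------------------------------------------- validation
    def validate(self, check_cavity: bool = True) -> None:
        """Raise :class:`MeshError` on violated structural invariants."""
        if np.any((self.cell_id < 0) & (self.side != SIDE_MEMBRANE)):
            raise MeshError("non-membrane face without a cell label")
        if np.any(self.face_areas() <= 0):
            raise MeshError("degenerate face with zero area")
        if len(self.vertices) > 1:
            q = np.round(self.vertices / _DUPLICATE_TOL).astype(np.int64)
            if len(np.unique(q, axis=0)) < len(q):
                raise MeshError("duplicate vertices within tolerance")
        if check_cavity:
            _check_closed(self.faces[self.cavity_face_mask])


# ---------------------------------------------------------------------------
def _edge_incidence(faces: np.ndarray):
    """Directed edges of a triangle soup: (sorted undirected key, direction)."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(e, axis=1)
    return e, key


def _check_closed(faces: np.ndarray, allow_pinched: bool = False) -> None:
    """Error unless each undirected edge is used exactly twice, once per direction.

    With ``allow_pinched=True`` an edge may be used any even number of times
    as long as the two directions balance — a watertight surface pinched
    along an edge (as can happen where a cell's label region touches a
    vertex from two sides).  Volume and pressure integrals remain exact on
    such surfaces.
    """
    if len(faces) == 0:
        raise MeshError("empty surface")
    e, key = _edge_incidence(faces)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                  return_counts=True)
    if allow_pinched:
        bad = uniq[counts % 2 != 0]
    else:
        bad = uniq[counts != 2]
    if len(bad):
        raise MeshError(
            f"surface not closed: {len(bad)} boundary/non-manifold edges, "
            f"e.g. {bad[:5].tolist()}")
    # orientation consistency: the two uses must be in opposite directions
    flip = (e[:, 0] < e[:, 1]).astype(np.int8)
    per_edge = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(per_edge, inv, 2 * flip - 1)
    if np.any(per_edge != 0):
        raise MeshError("inconsistently oriented surface")


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Volume of a closed triangulated surface by the divergence theorem.

    Orientation-insensitive (the magnitude is returned).  Raises
    :class:`MeshError` listing boundary edges if the surface is open.
    """
    faces = np.asarray(faces, dtype=np.int64)
    _check_closed(faces)
    v = np.asarray(vertices, dtype=float)
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    return abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def principal_axes(points: np.ndarray,
                   weights: np.ndarray | None = None) -> PrincipalAxes:
    """Principal axes of a (weighted) 3-D point set.

    Axes are eigenvectors of the covariance matrix about the (weighted)
    centroid; extents are the square roots of its eigenvalues, i.e.
    standard-deviation half-lengths, sorted descending.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise MeshError("principal_axes needs at least 4 points in 3-D")
    if weights is None:
        w = np.full(len(p), 1.0 / len(p))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    centroid = w @ p
    q = p - centroid
    cov = (q * w[:, None]).T @ q
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise MeshError("degenerate point set (zero covariance)")
    order = np.argsort(evals)[::-1]
    extents = np.sqrt(np.maximum(evals[order], 0.0))
    return PrincipalAxes(axes=evecs[:, order].T, extents=extents)
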
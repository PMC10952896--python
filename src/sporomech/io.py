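"""Mesh and field I/O.

Labeled shells round-trip through an ASCII PLY dialect that stores
``cell_id``, ``side`` and ``cell_id2`` as per-face integer properties.
Plain geometry can also be exported to OBJ (labels are not representable
there), and per-element scalar fields (principal stresses, von Mises) to
ASCII VTU for visualisation in ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .mesh import CellularShellMesh, MeshError


def save_ply(mesh: CellularShellMesh, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment sporomech cellular shell\n")
        fh.write(f"comment longitudinal_axis "
                 f"{' '.join(f'{c:.17g}' for c in mesh.longitudinal_axis)}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property int cell_id\nproperty int side\n"
                 "property int cell_id2\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f, c, s, c2 in zip(mesh.faces, mesh.cell_id, mesh.side,
                               mesh.cell_id2):
            fh.write(f"3 {f[0]} {f[1]} {f[2]} {c} {s} {c2}\n")


def load_ply(path) -> CellularShellMesh:
    path = Path(path)
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise MeshError(f"{path}: not a PLY file")
        n_v = n_f = 0
        axis = np.array([1.0, 0.0, 0.0])
        while True:
            line = fh.readline()
            if not line:
                raise MeshError(f"{path}: truncated header")
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "comment" and len(tok) == 5 \
                    and tok[1] == "longitudinal_axis":
                axis = np.array([float(t) for t in tok[2:5]])
            elif tok[0] == "element" and tok[1] == "vertex":
                n_v = int(tok[2])
            elif tok[0] == "element" and tok[1] == "face":
                n_f = int(tok[2])
            elif tok[0] == "end_header":
                break
        verts = np.array([fh.readline().split() for _ in range(n_v)],
                         dtype=float)
        faces = np.empty((n_f, 3), np.int64)
        cell = np.zeros(n_f, np.int64)
        side = np.zeros(n_f, np.int64)
        cell2 = np.full(n_f, -1, np.int64)
        for i in range(n_f):
            tok = fh.readline().split()
            if int(tok[0]) != 3:
                raise MeshError(f"{path}: only triangle faces are supported")
            faces[i] = [int(t) for t in tok[1:4]]
            if len(tok) >= 5:
                cell[i] = int(tok[4])
            if len(tok) >= 6:
                side[i] = int(tok[5])
            if len(tok) >= 7:
                cell2[i] = int(tok[6])
    return CellularShellMesh(vertices=verts, faces=faces, cell_id=cell,
                             side=side, cell_id2=cell2,
                             longitudinal_axis=axis)


def save_obj(mesh: CellularShellMesh, path) -> None:
    """Geometry-only OBJ export (labels are dropped)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    Path(path).write_text(trimesh.exchange.obj.export_obj(tm))


def save_vtu(mesh: CellularShellMesh, path,
             cell_data: dict[str, np.ndarray] | None = None,
             vertices: np.ndarray | None = None) -> None:
    """ASCII VTU (unstructured grid) with per-element scalar fields.

    ``cell_id`` and ``side`` are always written; extra fields (e.g. per-face
    stresses) go in ``cell_data``.  NaNs are preserved.
    """
    v = mesh.vertices if vertices is None else np.asarray(vertices, float)
    f = mesh.faces
    fields = {"cell_id": mesh.cell_id.astype(float),
              "side": mesh.side.astype(float)}
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr, float)
        if len(arr) != len(f):
            raise MeshError(f"cell_data field {name!r} has wrong length")
        fields[name] = arr

    def fmt(a):
        return " ".join(f"{x:.9g}" for x in np.asarray(a).ravel())

    with open(Path(path), "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        fh.write(f'<Piece NumberOfPoints="{len(v)}" NumberOfCells="{len(f)}">\n')
        fh.write('<Points>\n<DataArray type="Float64" '
                 'NumberOfComponents="3" format="ascii">\n')
        fh.write(fmt(v))
        fh.write('\n</DataArray>\n</Points>\n<Cells>\n')
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        fh.write(fmt(f))
        fh.write('\n</DataArray>\n'
                 '<DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write(fmt(3 * np.arange(1, len(f) + 1)))
        fh.write('\n</DataArray>\n'
                 '<DataArray type="UInt8" Name="types" format="ascii">\n')
        fh.write(fmt(np.full(len(f), 5)))          # VTK_TRIANGLE
        fh.write('\n</DataArray>\n</Cells>\n<CellData>\n')
        for name, arr in fields.items():
            fh.write(f'<DataArray type="Float64" Name="{name}" '
                     'format="ascii">\n')
            fh.write(fmt(arr))
            fh.write('\n</DataArray>\n')
        fh.write('</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n')
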
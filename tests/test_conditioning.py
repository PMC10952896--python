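"""Boundary smoothing, triangle-quality repair and inward extrusion."""

import numpy as np
import pytest

import sporomech as sm
from sporomech.mesh import SIDE_OUTER, CellularShellMesh, MeshError


def strip_mesh(ny: int = 5, displaced: float = 0.0) -> CellularShellMesh:
    """Flat strip: two cell bands meeting along the straight line y = 1.

    Vertices on three rows (y = 0, 1, 2), ``ny`` columns; the middle-row
    centre vertex can be displaced off the boundary line by ``displaced``.
    """
    xs = np.arange(ny, dtype=float)
    rows = [np.column_stack([xs, np.full(ny, y), np.zeros(ny)])
            for y in (0.0, 1.0, 2.0)]
    v = np.vstack(rows)
    mid = ny + ny // 2
    v[mid, 1] += displaced
    faces, cells = [], []
    for r, cell in ((0, 0), (1, 1)):
        o = r * ny
        for i in range(ny - 1):
            faces += [[o + i, o + i + 1, o + ny + i + 1],
                      [o + i, o + ny + i + 1, o + ny + i]]
            cells += [cell, cell]
    return CellularShellMesh(
        vertices=v, faces=np.array(faces, np.int64),
        cell_id=np.array(cells, np.int64),
        side=np.full(len(faces), SIDE_OUTER, np.int64))


class TestSmoothing:
    def test_zero_passes_is_identity(self):
        mesh = strip_mesh(displaced=0.3)
        out = sm.smooth_cell_boundaries(mesh, passes=0)
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_displaced_vertex_pulled_back_and_monotone(self):
        mid = 5 + 2
        prev = 0.3
        for passes in (1, 2, 3):
            out = sm.smooth_cell_boundaries(strip_mesh(displaced=0.3),
                                            passes=passes)
            disp = abs(out.vertices[mid, 1] - 1.0)
            assert disp < prev  # strictly decreasing with each pass
            prev = disp

    def test_collinear_boundary_is_fixed_point(self):
        mesh = strip_mesh(displaced=0.0)
        out = sm.smooth_cell_boundaries(mesh, passes=3)
        assert np.allclose(out.vertices, mesh.vertices, atol=1e-9)

    def test_labels_and_topology_unchanged(self):
        mesh = strip_mesh(displaced=0.3)
        out = sm.smooth_cell_boundaries(mesh, passes=3)
        assert np.array_equal(out.faces, mesh.faces)
        assert np.array_equal(out.cell_id, mesh.cell_id)


class TestAspectRatio:
    def test_equilateral_scores_one(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        ar = sm.triangle_aspect_ratio(v, [[0, 1, 2]])
        assert ar[0] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_with_sliverness(self):
        heights = [0.8, 0.4, 0.1, 0.02]
        ars = [sm.triangle_aspect_ratio(
            np.array([[0, 0, 0], [1, 0, 0], [0.5, h, 0]]), [[0, 1, 2]])[0]
            for h in heights]
        assert np.all(np.diff(ars) > 0)


def slivered_sphere():
    """Closed sheared loft: every quad's default diagonal is the long one.

    A 35° helical shear of the rings turns the near-square faces into
    parallelograms whose fixed-diagonal triangulation is all slivers
    (aspect ratio > 2) — the very population the merge/retriangulate
    repair targets.
    """
    from sporomech.generate import _shear_table
    spec = sm.preset("spherical", base_opening=0.0, jitter_sigma=0.0,
                     file_tilt=35.0, cell_rows=2, cell_cols=4, n_theta=48)
    cs = sm.cross_section_contour(spec)
    prof = sm.profile_curve(spec)
    x_p, r_p = prof[:, 0], prof[:, 1]
    seg = np.hypot(np.diff(x_p), np.diff(r_p))
    L = seg.sum()
    perim = np.sum(np.linalg.norm(
        np.diff(np.vstack([cs, cs[:1]]), axis=0), axis=1))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    r_mean = np.trapezoid(r_p, arc) / L
    n_rows = max(3, int(round(L * len(cs) / (perim * r_mean))))
    s = np.linspace(0.0, L, n_rows + 1)
    _, arc_t, shear = _shear_table(spec)
    return sm.loft_surface(cs, prof, s_positions=s,
                           ring_offsets=np.interp(s, arc_t, shear))


class TestRepair:
    def test_good_mesh_unchanged(self):
        mesh = strip_mesh()
        out = sm.repair_triangle_quality(mesh)
        assert np.array_equal(out.faces, mesh.faces)

    def test_sliver_count_halved_on_fixture(self):
        mesh = slivered_sphere()
        before = (sm.triangle_aspect_ratio(mesh.vertices, mesh.faces)
                  > 2.0).sum()
        assert before >= 100   # the fixture seeds plenty of offenders
        out = sm.repair_triangle_quality(mesh, max_aspect=2.0, passes=3)
        after = (sm.triangle_aspect_ratio(out.vertices, out.faces)
                 > 2.0).sum()
        assert after <= 0.5 * before

    def test_volume_and_labels_preserved(self):
        mesh = slivered_sphere()
        vol0 = sm.enclosed_volume(mesh.vertices, mesh.faces)
        out = sm.repair_triangle_quality(mesh)
        vol1 = sm.enclosed_volume(out.vertices, out.faces)
        assert vol1 == pytest.approx(vol0, rel=5e-3)
        assert set(np.unique(out.cell_id)) == set(np.unique(mesh.cell_id))

    def test_offender_count_never_increases(self):
        mesh = slivered_sphere()
        prev = (sm.triangle_aspect_ratio(mesh.vertices, mesh.faces)
                > 2.0).sum()
        for _ in range(3):
            mesh = sm.repair_triangle_quality(mesh, passes=1)
            cur = (sm.triangle_aspect_ratio(mesh.vertices, mesh.faces)
                   > 2.0).sum()
            assert cur <= prev
            prev = cur


class TestExtrusion:
    def test_zero_depth_rejected(self):
        with pytest.raises(MeshError, match="positive"):
            sm.extrude_cells(strip_mesh(), depth=0.0)

    def test_square_cell_prism_volume(self):
        v = np.array([[0, 0, 0], [100, 0, 0], [100, 100, 0], [0, 100, 0]],
                     float)
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        surf = CellularShellMesh(
            vertices=v, faces=faces, cell_id=np.zeros(2, int),
            side=np.full(2, SIDE_OUTER, int))
        mesh = sm.extrude_cells(surf, depth=8.0)
        vols = mesh.cell_volumes()
        assert vols[0] == pytest.approx(100 * 100 * 8, rel=0.01)

    def test_spherical_shell_volume(self):
        import trimesh
        tm = trimesh.creation.icosphere(subdivisions=3, radius=200.0)
        surf = CellularShellMesh(
            vertices=np.asarray(tm.vertices, float),
            faces=np.asarray(tm.faces, np.int64),
            cell_id=np.zeros(len(tm.faces), np.int64),
            side=np.full(len(tm.faces), SIDE_OUTER, np.int64))
        mesh = sm.extrude_cells(surf, depth=8.0)
        wall = mesh.cell_volumes()[0]
        exact = 4 / 3 * np.pi * (200 ** 3 - 192 ** 3)
        assert wall == pytest.approx(exact, rel=0.02)

    def test_excessive_depth_reports_cell(self):
        import trimesh
        tm = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        surf = CellularShellMesh(
            vertices=np.asarray(tm.vertices, float),
            faces=np.asarray(tm.faces, np.int64),
            cell_id=np.zeros(len(tm.faces), np.int64),
            side=np.full(len(tm.faces), SIDE_OUTER, np.int64))
        with pytest.raises(MeshError, match="cell 0"):
            sm.extrude_cells(surf, depth=15.0)

    def test_compartments_watertight(self):
        mesh = sm.build_specimen(sm.preset("spherical", rng_seed=0))
        vols = mesh.cell_volumes()
        assert np.all(vols > 0)
        assert len(vols) == len(mesh.cells)
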
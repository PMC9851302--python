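import numpy as np
import pytest

from voxmesh import fixtures
from voxmesh import mesh_core as mc
from voxmesh.mesh_core import SurfaceMesh

from conftest import random_small_mesh


class TestTriangulateNgons:
    def test_quad_fan(self):
        out = mc.triangulate_ngons([(0, 1, 2, 3)])
        assert out.tolist() == [[0, 1, 2], [0, 2, 3]]

    def test_triangle_identity(self):
        assert mc.triangulate_ngons([(4, 5, 6)]).tolist() == [[4, 5, 6]]

    def test_hexagon_yields_n_minus_2(self):
        assert len(mc.triangulate_ngons([tuple(range(6))])) == 4

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mc.triangulate_ngons([(0, 1)])


class TestTopology:
    def test_single_triangle(self, single_triangle):
        topo = mc.build_topology(single_triangle)
        assert len(topo.edges) == 3
        assert all(len(ts) == 1 for ts in topo.edge_tri)

    def test_tetrahedron_closed(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        tris = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        topo = mc.build_topology(SurfaceMesh(verts, tris))
        assert len(topo.edges) == 6
        assert all(len(ts) == 2 for ts in topo.edge_tri)

    def test_edge_incidence_sums_to_3f(self, icosphere):
        topo = mc.build_topology(icosphere)
        assert topo.edge_counts.sum() == 3 * icosphere.n_triangles


class TestDefectDetectors:
    def test_hole_gives_3_boundary_edges(self):
        ico = fixtures.make_icosphere(1.0, 0)
        holed = SurfaceMesh(ico.vertices, ico.triangles[1:])
        topo = mc.build_topology(holed)
        assert len(mc.boundary_edges(topo)) == 3

    def test_three_triangles_on_one_edge(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [0, -1, 0.0]])
        tris = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])
        topo = mc.build_topology(SurfaceMesh(verts, tris))
        assert len(mc.non_manifold_edges(topo)) == 1

    def test_two_tets_glued_at_vertex(self):
        # two closed tetrahedra sharing exactly one vertex: fan breaks there
        v1 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        v2 = v1 * -1.0
        verts = np.vstack([v1, v2[1:]])  # shared vertex 0
        t = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        t2 = np.array([[0, 4, 5], [0, 4, 6], [0, 5, 6], [4, 5, 6]])
        mesh = SurfaceMesh(verts, np.vstack([t, t2]))
        topo = mc.build_topology(mesh)
        bad = mc.non_manifold_vertices(mesh, topo)
        assert bad.tolist() == [0]

    def test_floating_vertex_reported_but_not_leaky(self, single_triangle):
        mesh = SurfaceMesh(np.vstack([single_triangle.vertices, [[5, 5, 5]]]),
                           single_triangle.triangles)
        topo = mc.build_topology(mesh)
        assert mc.floating_vertices(mesh, topo).tolist() == [3]


class TestSelfIntersections:
    def test_disjoint_triangles_empty(self):
        mesh = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                                     [10, 10, 10], [11, 10, 10], [10, 11, 10.0]]),
                           np.array([[0, 1, 2], [3, 4, 5]]))
        assert mc.self_intersections(mesh) == []

    def test_closed_icosphere_clean(self, icosphere):
        assert mc.self_intersections(icosphere) == []

    def test_interpenetrating_spheres_match_bruteforce(self):
        a = fixtures.make_icosphere(1.0, 1)
        b = fixtures.make_icosphere(1.0, 1, center=(0.8, 0.1, 0.0))
        soup = SurfaceMesh(np.vstack([a.vertices, b.vertices]),
                           np.vstack([a.triangles, b.triangles + a.n_vertices]))
        fast = mc.self_intersections(soup)
        assert fast  # they do interpenetrate
        assert fast == mc.self_intersections_brute(soup)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_soups_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        mesh = random_small_mesh(rng, n_tris=12)
        assert mc.self_intersections(mesh) == mc.self_intersections_brute(mesh)


class TestPartitions:
    def test_two_disjoint_spheres(self):
        a = fixtures.make_icosphere(1.0, 1)
        b = fixtures.make_icosphere(1.0, 1, center=(5.0, 0, 0))
        soup = SurfaceMesh(np.vstack([a.vertices, b.vertices]),
                           np.vstack([a.triangles, b.triangles + a.n_vertices]))
        assert len(mc.split_partitions(soup)) == 2

    def test_torus_single_partition(self, torus):
        assert len(mc.split_partitions(torus)) == 1

    def test_isolated_triangles(self):
        rng = np.random.default_rng(0)
        k = 7
        mesh = SurfaceMesh(rng.random((3 * k, 3)) * 100,
                           np.arange(3 * k).reshape(-1, 3))
        assert len(mc.split_partitions(mesh)) == k

    def test_triangle_count_conserved(self, torus):
        parts = mc.split_partitions(torus)
        assert sum(p.n_triangles for p in parts) == torus.n_triangles

    def test_euler_characteristic(self, icosphere, torus):
        for mesh, chi in [(icosphere, 2), (torus, 0)]:
            topo = mc.build_topology(mesh)
            assert mesh.n_vertices - len(topo.edges) + mesh.n_triangles == chi


class TestWatertightnessReport:
    def test_closed_icosahedron(self):
        rep = mc.watertightness_report(fixtures.make_icosphere(1.0, 0))
        assert rep.is_watertight
        assert rep.n_partitions == 1

    def test_missing_face(self):
        ico = fixtures.make_icosphere(1.0, 0)
        rep = mc.watertightness_report(SurfaceMesh(ico.vertices, ico.triangles[1:]))
        assert rep.n_boundary_edges == 3
        assert not rep.is_watertight

    def test_overlapping_spheres_not_watertight(self):
        a = fixtures.make_icosphere(1.0, 1)
        b = fixtures.make_icosphere(1.0, 1, center=(0.9, 0, 0))
        soup = SurfaceMesh(np.vstack([a.vertices, b.vertices]),
                           np.vstack([a.triangles, b.triangles + a.n_vertices]))
        rep = mc.watertightness_report(soup)
        assert rep.n_self_intersections > 0
        assert not rep.is_watertight


class TestMeasures:
    def test_unit_cube(self, unit_cube):
        assert mc.enclosed_volume(unit_cube) == pytest.approx(1.0)
        assert mc.surface_area(unit_cube) == pytest.approx(6.0)

    def test_icosphere_volume_below_and_near_ball(self):
        ico = fixtures.make_icosphere(1.0, 3)
        v = mc.enclosed_volume(ico)
        ball = 4 * np.pi / 3
        assert v < ball
        assert v == pytest.approx(ball, rel=0.02)

    def test_rigid_invariance(self, icosphere):
        moved = icosphere.translated([3.0, -2.0, 7.5])
        assert mc.enclosed_volume(moved) == pytest.approx(
            mc.enclosed_volume(icosphere))
        assert mc.surface_area(moved) == pytest.approx(
            mc.surface_area(icosphere))

    def test_volume_convergence_with_subdivision(self):
        vols = [mc.enclosed_volume(fixtures.make_icosphere(1.0, s))
                for s in range(4)]
        assert all(a < b for a, b in zip(vols, vols[1:]))
        assert vols[-1] < 4 * np.pi / 3

    def test_open_mesh_volume_rejected(self, single_triangle):
        with pytest.raises(ValueError, match="closed"):
            mc.enclosed_volume(single_triangle)


class TestHausdorff:
    def test_self_distance_zero(self, icosphere):
        assert mc.hausdorff_distance(icosphere, icosphere, 200) < 1e-12

    def test_far_translation_equals_offset(self, icosphere):
        d = 100.0
        moved = icosphere.translated([d, 0, 0])
        got = mc.hausdorff_distance(icosphere, moved, 500)
        assert got == pytest.approx(d, rel=0.01)

    def test_concentric_spheres(self):
        a = fixtures.make_icosphere(1.0, 3)
        b = fixtures.make_icosphere(2.0, 3)
        got = mc.hausdorff_distance(a, b, 500)
        assert got == pytest.approx(1.0, abs=0.03)

    def test_empty_rejected(self, icosphere):
        empty = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), np.int64))
        with pytest.raises(ValueError):
            mc.hausdorff_distance(icosphere, empty)


class TestTetBoundary:
    def test_single_tet(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        out = mc.extract_tet_boundary([(0, 1, 2, 3)], verts)
        assert out.n_triangles == 4
        assert mc.watertightness_report(out).is_watertight

    def test_two_tets_share_face(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1, 1, 1.0]])
        out = mc.extract_tet_boundary([(0, 1, 2, 3), (1, 2, 3, 4)], verts)
        assert out.n_triangles == 6

    def test_cube_decomposition(self):
        # 5-tet decomposition of the unit cube: boundary = 12 faces, volume 1
        v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                     dtype=float)
        tets = [(0, 1, 2, 4), (1, 2, 3, 7), (1, 4, 5, 7), (2, 4, 6, 7),
                (1, 2, 4, 7)]
        out = mc.extract_tet_boundary(tets, v)
        assert out.n_triangles == 12
        assert mc.enclosed_volume(out) == pytest.approx(1.0)
        assert mc.watertightness_report(out).is_watertight


class TestWeldAndDegenerate:
    def test_weld_merges_close_vertices(self):
        mesh = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                                     [1e-9, 0, 0], [1, 1, 0.0]]),
                           np.array([[0, 1, 2], [3, 1, 4]]))
        welded = mc.weld_vertices(mesh)
        assert welded.n_vertices == 4
        topo = mc.build_topology(welded)
        # edge (0,1) now shared by both triangles
        assert int(topo.edge_counts.max()) == 2

    def test_drop_duplicates_and_degenerates(self):
        mesh = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
                           np.array([[0, 1, 2], [0, 1, 2], [1, 0, 2], [0, 0, 1]]))
        out, n_degen, n_dup = mc.drop_degenerate_triangles(mesh)
        assert out.n_triangles == 1
        assert n_degen == 1       # the repeated-index triangle
        assert n_dup == 2         # exact duplicate + rewound duplicate
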
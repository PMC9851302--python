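import numpy as np
import pytest

from voxmesh import fixtures
from voxmesh import mesh_core as mc
from voxmesh import morphology as mo
from voxmesh.volume_grid import BitVolumeGrid, GridSpec


def section(radii, spacing=1.0, sid=0):
    samples = [mo.Sample((i * spacing, 0.0, 0.0), r) for i, r in enumerate(radii)]
    return mo.Section(sid, samples)


def catmull_rom_point_oracle(p0, p1, p2, p3, u, alpha=0.5):
    """Independent closed-form centripetal Catmull–Rom evaluation between
    p1 and p2 via the recursive De Boor-style pyramid (Barry–Goldman)."""
    p = [np.asarray(x, dtype=float) for x in (p0, p1, p2, p3)]
    t = [0.0]
    for a, b in zip(p, p[1:]):
        t.append(t[-1] + np.linalg.norm(b - a) ** alpha)
    tt = t[1] + u * (t[2] - t[1])

    def lerp(ta, tb, pa, pb):
        if tb == ta:
            return pa
        return (tb - tt) / (tb - ta) * pa + (tt - ta) / (tb - ta) * pb

    a1 = lerp(t[0], t[1], p[0], p[1])
    a2 = lerp(t[1], t[2], p[1], p[2])
    a3 = lerp(t[2], t[3], p[2], p[3])
    b1 = lerp(t[0], t[2], a1, a2)
    b2 = lerp(t[1], t[3], a2, a3)
    return lerp(t[1], t[2], b1, b2)


class TestRepairSkeleton:
    def _wrap(self, sec):
        return mo.Morphology({sec.id: sec})

    def test_zero_radius_interpolated(self):
        m = mo.repair_skeleton(self._wrap(section([1.0, 0.0, 1.0])))
        assert m.sections[0].radii == pytest.approx([1, 1, 1])

    def test_duplicate_positions_merged(self):
        samples = [mo.Sample((0, 0, 0), 1), mo.Sample((0, 0, 0), 2),
                   mo.Sample((1, 0, 0), 1)]
        m = mo.repair_skeleton(self._wrap(mo.Section(0, samples)))
        assert len(m.sections[0].samples) == 2
        assert m.sections[0].samples[0].radius == 2  # max of merged pair

    def test_median_filter_kills_spike(self):
        m = mo.repair_skeleton(self._wrap(section([1, 1, 9, 1, 1])))
        assert m.sections[0].radii == pytest.approx([1, 1, 1, 1, 1])

    def test_all_zero_radii_rejected(self):
        with pytest.raises(mo.MorphologyStructureError):
            mo.repair_skeleton(self._wrap(section([0.0, 0.0, 0.0])))


class TestResampleAdaptive:
    def test_dense_collinear_reduced(self):
        sec = section([1.0] * 100, spacing=0.1)
        out = mo.resample_adaptive(sec)
        pos = out.positions
        gaps = np.linalg.norm(np.diff(pos[:-1], axis=0), axis=1)
        assert np.all(gaps > 1.0 - 1e-9)
        assert len(out.samples) <= 0.4 * 100        # >= 60% reduction

    def test_two_samples_unchanged(self):
        sec = section([1.0, 1.0])
        assert len(mo.resample_adaptive(sec).samples) == 2

    def test_already_sparse_unchanged(self):
        sec = section([0.5, 0.5, 0.5], spacing=2.0)
        out = mo.resample_adaptive(sec)
        assert len(out.samples) == 3

    def test_kept_samples_not_moved_endpoints_kept(self):
        sec = section([0.7] * 20, spacing=0.3)
        out = mo.resample_adaptive(sec)
        orig = {tuple(s.position) for s in sec.samples}
        assert all(tuple(s.position) in orig for s in out.samples)
        assert tuple(out.samples[0].position) == tuple(sec.samples[0].position)
        assert tuple(out.samples[-1].position) == tuple(sec.samples[-1].position)


class TestInterpolatePath:
    def test_endpoints_reproduced_exactly(self):
        samples = [mo.Sample((0, 0, 0), 1), mo.Sample((1, 1, 0), 2),
                   mo.Sample((2, 0, 0), 1)]
        out = mo.interpolate_path(samples, step=0.1)
        assert np.allclose(out[0].position, (0, 0, 0))
        assert np.allclose(out[-1].position, (2, 0, 0))
        positions = np.asarray([s.position for s in out])
        for s in samples:
            assert np.min(np.linalg.norm(positions - s.position, axis=1)) < 1e-9

    def test_collinear_knots_stay_collinear(self):
        samples = [mo.Sample((i, 2 * i, 0), 1) for i in range(5)]
        out = mo.interpolate_path(samples, step=0.05)
        pos = np.asarray([s.position for s in out])
        d = pos / np.maximum(np.linalg.norm(pos, axis=1, keepdims=True), 1e-12)
        assert np.allclose(pos[:, 1], 2 * pos[:, 0], atol=1e-9)
        assert np.allclose(pos[:, 2], 0, atol=1e-12)

    def test_matches_catmull_rom_oracle_on_interior_segment(self):
        knots = np.array([[0, 0, 0], [1, 1, 0], [2, -0.5, 0.5], [3.5, 0.3, -0.2]])
        samples = [mo.Sample(p, 1.0) for p in knots]
        # dense evaluation of the interior Hermite segment p1->p2
        tan, t = mo.catmull_rom_tangents(knots)
        us = np.linspace(0, 1, 17)
        got = mo._hermite(knots[1], knots[2], tan[1], tan[2], t[2] - t[1], us)
        want = np.asarray([catmull_rom_point_oracle(*knots, u) for u in us])
        assert np.allclose(got, want, atol=1e-9)

    def test_spacing_bound_respected(self):
        samples = [mo.Sample((0, 0, 0), 1), mo.Sample((0, 3, 1), 1),
                   mo.Sample((2, 4, 0), 1)]
        out = mo.interpolate_path(samples, step=0.2)
        pos = np.asarray([s.position for s in out])
        gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        # chord subdivision guarantees <= step per segment up to curvature slack
        assert gaps.max() < 0.2 * 1.6


class TestSweepTube:
    def test_cylinder_lateral_area(self):
        path = [mo.Sample((0, 0, z), 0.5) for z in np.linspace(0, 4, 21)]
        tube = mo.sweep_tube(path, n_ring=32)
        area = mc.surface_area(tube)
        lateral = 2 * np.pi * 0.5 * 4
        caps = 2 * np.pi * 0.5 ** 2
        assert area == pytest.approx(lateral + caps, rel=0.02)

    def test_vertex_count_formula(self):
        path = [mo.Sample((0, 0, z), 0.5) for z in range(5)]
        tube = mo.sweep_tube(path, n_ring=12)
        assert tube.n_vertices == 12 * 5 + 2

    def test_bend_no_self_crossing(self):
        # 90-degree elbow with ring spacing below the radius
        pts = [(x, 0, 0) for x in np.arange(0, 2, 0.4)]
        pts += [(2 + np.sin(a) * 0.8, 0, 0.8 - np.cos(a) * 0.8)
                for a in np.linspace(0.3, np.pi / 2, 5)]
        pts += [(2.8, 0, z) for z in np.arange(1.2, 3, 0.4)]
        path = [mo.Sample(p, 0.5) for p in pts]
        tube = mo.sweep_tube(path, n_ring=12)
        assert mc.self_intersections(tube) == []

    def test_bad_ring_count(self):
        with pytest.raises(ValueError):
            mo.sweep_tube([mo.Sample((0, 0, 0), 1), mo.Sample((1, 0, 0), 1)], 2)


class TestBuildPaths:
    def _tree(self, edges, soma=None):
        sections = {}
        for sid, (parent, pts) in edges.items():
            sections[sid] = mo.Section(sid, [mo.Sample(p, 0.5) for p in pts],
                                       parent)
        for sid, sec in sections.items():
            if sec.parent is not None:
                sections[sec.parent].children.append(sid)
        return mo.Morphology(sections, "neuron", soma)

    def test_single_section_single_path(self):
        m = self._tree({0: (None, [(0, 0, 0), (1, 0, 0)])})
        assert len(mo.build_paths(m)) == 1

    def test_bifurcation_two_paths(self):
        m = self._tree({0: (None, [(0, 0, 0), (1, 0, 0)]),
                        1: (0, [(1, 0, 0), (2, 1, 0)]),
                        2: (0, [(1, 0, 0), (2, -1, 0)])})
        paths = mo.build_paths(m)
        assert len(paths) == 2
        for p in paths:
            assert len(p) == 3      # shared sample appears once per path

    def test_binary_tree_depth3_eight_paths(self):
        edges = {0: (None, [(0, 0, 0), (1, 0, 0)])}
        nid = 1
        frontier = [0]
        for level in range(3):
            nxt = []
            for parent in frontier:
                for sgn in (1, -1):
                    x = edges[parent][1][-1]
                    edges[nid] = (parent, [x, (x[0] + 1, x[1] + sgn * 0.5, 0)])
                    nxt.append(nid)
                    nid += 1
            frontier = nxt
        m = self._tree(edges)
        assert len(mo.build_paths(m)) == 8

    def test_soma_prepended(self):
        soma = mo.Soma(np.array([-1.0, 0, 0]), 1.0, [0])
        m = self._tree({0: (None, [(0, 0, 0), (1, 0, 0)])}, soma)
        paths = mo.build_paths(m)
        assert np.allclose(paths[0][0].position, [-1, 0, 0])


class TestPerSectionProxies:
    def test_packing_sphere_radius_is_max_terminal(self):
        node = (1.0, 0.0, 0.0)
        sections = {
            0: mo.Section(0, [mo.Sample((0, 0, 0), 1.0), mo.Sample(node, 1.0)]),
            1: mo.Section(1, [mo.Sample(node, 2.0), mo.Sample((2, 1, 0), 1.0)]),
            2: mo.Section(2, [mo.Sample(node, 1.5), mo.Sample((2, -1, 0), 1.0)]),
        }
        m = mo.Morphology(sections, "vasculature")
        radii = mo.branch_point_radii(m)
        assert radii[tuple(np.round(node, 9))] == 2.0

    def test_chain_shared_node_gets_one_sphere(self):
        node = (1.0, 0, 0)
        sections = {0: mo.Section(0, [mo.Sample((0, 0, 0), 1), mo.Sample(node, 1)]),
                    1: mo.Section(1, [mo.Sample(node, 1), mo.Sample((2, 0, 0), 1)])}
        m = mo.Morphology(sections, "vasculature")
        assert len(mo.branch_point_radii(m)) == 1

    def test_loop_gets_sphere_per_junction(self, tmp_path):
        from voxmesh import io_formats as io
        p = tmp_path / "v.swc"
        p.write_text(fixtures.make_vessel_graph(seed=0, n_loops=2))
        m = io.read_swc(str(p), "vasculature")
        proxies = mo.per_section_proxies(m, n_ring=8)
        n_junctions = len(mo.branch_point_radii(m))
        assert len(proxies) == len(m.sections) + n_junctions


class TestReconstructSoma:
    def _neuron(self, directions):
        sections = {}
        for i, d in enumerate(directions):
            d = np.asarray(d, dtype=float)
            sections[i] = mo.Section(i, [mo.Sample(2.0 * d, 0.6),
                                         mo.Sample(4.0 * d, 0.5)], None)
        soma = mo.Soma(np.zeros(3), 1.5, list(sections))
        return mo.Morphology(sections, "neuron", soma)

    def test_no_neurites_plain_icosphere(self):
        m = mo.Morphology({}, "neuron", mo.Soma(np.zeros(3), 1.0, []))
        with pytest.warns(UserWarning):
            mesh = mo.reconstruct_soma(m)
        ref = mo.make_icosphere_mesh(1.0, 3)
        assert mc.enclosed_volume(mesh) == pytest.approx(mc.enclosed_volume(ref))

    def test_volume_preserved_within_1pct(self):
        m = self._neuron([(1, 0, 0), (0, 1, 0), (-0.5, -0.5, 0.7)])
        mesh = mo.reconstruct_soma(m)
        ref = mo.make_icosphere_mesh(1.5, 3)
        assert mc.enclosed_volume(mesh) == pytest.approx(
            mc.enclosed_volume(ref), rel=0.01)

    def test_opposite_neurites_symmetric(self):
        m = self._neuron([(1, 0, 0), (-1, 0, 0)])
        mesh = mo.reconstruct_soma(m)
        flipped = mesh.vertices * np.array([-1, 1, 1])
        # vertex sets agree under the 180-degree rotation swapping the two
        from scipy.spatial import cKDTree
        d, _ = cKDTree(mesh.vertices).query(flipped)
        assert d.max() < 1e-6

    def test_bulges_toward_neurite(self):
        m = self._neuron([(1, 0, 0)])
        mesh = mo.reconstruct_soma(m)
        xmax = mesh.vertices[:, 0].max()
        assert xmax > 1.5 * 1.05     # stretched toward +x


class TestEndfeetProxy:
    def _grid(self, h=0.25):
        spec = GridSpec((-4, -4, -4), h, (32, 32, 32))
        return BitVolumeGrid(spec)

    def test_single_patch_one_connected_component(self):
        from scipy import ndimage
        patch = mo.EndfootPatch(np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0.0]]),
                                np.array([1.0, 1.0, 1.0]),
                                np.array([[0, 1, 2]]))
        grid = self._grid(h=0.25)   # thickness 1.0 >= 2 voxels
        mo.endfeet_proxy([patch], grid)
        labels, n = ndimage.label(grid.data,
                                  structure=np.ones((3, 3, 3), dtype=bool))
        assert n == 1

    def test_long_edge_subdivided(self):
        t = 0.5
        patch = mo.EndfootPatch(np.array([[0, 0, 0], [10 * t, 0, 0], [0, t, 0.0]]),
                                np.array([t, t, t]), np.array([[0, 1, 2]]))
        verts, thick, tris = mo._subdivide_patch(patch)
        # all edges now within local thickness
        for a, b, c in tris:
            for u, v in ((a, b), (b, c), (c, a)):
                limit = min(thick[u], thick[v])
                assert np.linalg.norm(verts[u] - verts[v]) <= limit + 1e-9

    def test_empty_patch_list_noop(self):
        grid = self._grid()
        mo.endfeet_proxy([], grid)
        assert not grid.data.any()


class TestNeuriteConnectivity:
    def _morph(self, first_pos, soma_radius=1.0):
        sec = mo.Section(0, [mo.Sample(first_pos, 0.5),
                             mo.Sample((10, 0, 0), 0.5)], None)
        soma = mo.Soma(np.zeros(3), soma_radius, [0])
        return mo.Morphology({0: sec}, "neuron", soma)

    def test_close_root_connected(self):
        connected, bridges = mo.neurite_connectivity(self._morph((1.1, 0, 0)))
        assert connected == [0] and not bridges

    def test_far_root_bridged(self):
        connected, bridges = mo.neurite_connectivity(self._morph((5.0, 0, 0)))
        assert not connected
        assert len(bridges) == 1
        (sid, seg) = bridges[0]
        assert sid == 0
        assert np.allclose(seg[0].position, (0, 0, 0))

    def test_no_soma_fallback_warns(self):
        sec = mo.Section(0, [mo.Sample((0, 0, 0), 0.5),
                             mo.Sample((1, 0, 0), 0.5)], None)
        m = mo.Morphology({0: sec}, "neuron", None)
        with pytest.warns(UserWarning):
            connected, bridges = mo.neurite_connectivity(m)
        assert len(bridges) == 1
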
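"""Deterministic synthetic fixtures: meshes, broken soups, skeletons, masks.

Every generator is a pure function of its arguments (seeded where random),
so the full test and acceptance battery runs without any external data.
The closed primitives carry known topology and analytic measures:
icosphere (χ=2, volume → 4πr³/3 with subdivision), torus (χ=0, volume
2π²Rr²), box (χ=2, volume = product of extents).

``break_mesh`` emulates the defect classes of segmented EM meshes:
deleted faces (boundary edges / gaps), duplicated faces, vertex jitter
(cracks between formerly shared corners) and shifted overlapping copies
(self-intersecting partitions).
"""

from __future__ import annotations

import numpy as np

from .mesh_core import SurfaceMesh
from .morphology import make_icosphere_mesh
from .volume_grid import BitVolumeGrid, GridSpec

__all__ = [
    "make_icosphere",
    "make_torus",
    "make_box",
    "break_mesh",
    "make_neuron_swc",
    "make_vessel_graph",
    "make_astrocyte",
    "make_ball_mask",
]


def make_icosphere(radius: float = 1.0, subdivisions: int = 3,
                   center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Geodesic icosphere; subdivision 0 is the 12-vertex icosahedron."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return make_icosphere_mesh(radius, subdivisions, center)


def make_torus(major_radius: float = 2.0, minor_radius: float = 0.6,
               n_major: int = 48, n_minor: int = 24) -> SurfaceMesh:
    """Closed torus around the z axis: χ = 0, volume 2π²Rr²."""
    if not (major_radius > minor_radius > 0):
        raise ValueError("need major_radius > minor_radius > 0")
    u = 2 * np.pi * np.arange(n_major) / n_major
    v = 2 * np.pi * np.arange(n_minor) / n_minor
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (major_radius + minor_radius * np.cos(vv)) * np.cos(uu)
    y = (major_radius + minor_radius * np.cos(vv)) * np.sin(uu)
    z = minor_radius * np.sin(vv)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    tris = []
    for i in range(n_major):
        for j in range(n_minor):
            a = i * n_minor + j
            b = ((i + 1) % n_major) * n_minor + j
            c = ((i + 1) % n_major) * n_minor + (j + 1) % n_minor
            d = i * n_minor + (j + 1) % n_minor
            tris += [(a, b, c), (a, c, d)]
    return SurfaceMesh(verts, np.asarray(tris, dtype=np.int64))


def make_box(extent=(1.0, 1.0, 1.0), center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Axis-aligned box as 12 triangles."""
    e = np.asarray(extent, dtype=float) / 2.0
    c = np.asarray(center, dtype=float)
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                        for sz in (-1, 1)], dtype=float) * e + c
    quads = [(0, 1, 3, 2), (4, 6, 7, 5), (0, 4, 5, 1),
             (2, 3, 7, 6), (0, 2, 6, 4), (1, 5, 7, 3)]
    tris = []
    for q in quads:
        tris += [(q[0], q[1], q[2]), (q[0], q[2], q[3])]
    return SurfaceMesh(corners, np.asarray(tris, dtype=np.int64))


def break_mesh(mesh: SurfaceMesh, seed: int = 0, del_frac: float = 0.0,
               dup_frac: float = 0.0, jitter: float = 0.0,
               n_shift_partitions: int = 0,
               shift_scale: float = 0.5) -> SurfaceMesh:
    """Damage a closed mesh into a defective triangle soup (seeded).

    del_frac/dup_frac: fraction of faces deleted/duplicated; jitter:
    σ of Gaussian noise (μm) applied to unshared per-face corner copies;
    n_shift_partitions: overlapping shifted copies of the whole mesh
    (offset = shift_scale · mean |vertex| along a random direction).
    """
    if not (0 <= del_frac <= 1 and 0 <= dup_frac <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    verts = mesh.vertices.copy()
    tris = mesh.triangles.copy()
    if del_frac > 0:
        n_del = max(1, int(round(del_frac * len(tris))))
        kill = rng.choice(len(tris), size=n_del, replace=False)
        keep = np.ones(len(tris), dtype=bool)
        keep[kill] = False
        tris = tris[keep]
    if dup_frac > 0:
        n_dup = max(1, int(round(dup_frac * len(tris))))
        dup = rng.choice(len(tris), size=n_dup, replace=False)
        tris = np.vstack([tris, tris[dup]])
    if jitter > 0:
        verts = verts + rng.normal(0.0, jitter, size=verts.shape)
    parts_v, parts_t = [verts], [tris]
    scale = np.abs(mesh.vertices).mean()
    for _ in range(n_shift_partitions):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        off = shift_scale * scale * direction
        parts_t.append(mesh.triangles + sum(len(v) for v in parts_v))
        parts_v.append(mesh.vertices + off)
    return SurfaceMesh(np.vstack(parts_v), np.vstack(parts_t))


# ---------------------------------------------------------------------------
# morphology fixtures

def make_neuron_swc(seed: int = 0, depth: int = 3, branch_prob: float = 1.0,
                    taper: float = 0.8, soma_radius: float = 2.0,
                    section_length: float = 6.0, n_samples: int = 5) -> str:
    """Synthetic neuron SWC text: type-1 soma block plus a binary tree.

    A single stem leaves the soma; at every level each tip bifurcates with
    probability ``branch_prob`` until ``depth`` levels; radii taper by
    ``taper`` per level.  ``depth=1, branch_prob=1`` yields exactly two
    leaf sections.
    """
    rng = np.random.default_rng(seed)
    lines = ["# synthetic neuron morphology",
             f"1 1 0 0 0 {soma_radius} -1"]
    next_id = 3

    def grow(parent_id, origin, direction, radius, level):
        nonlocal next_id
        direction = direction / np.linalg.norm(direction)
        step = section_length / (n_samples - 1)
        pid = parent_id
        pos = origin.copy()
        for k in range(1, n_samples):
            pos = origin + direction * step * k
            wig = rng.normal(0, 0.08 * step, 3)
            p = pos + (wig if k < n_samples - 1 else 0)
            lines.append(f"{next_id} 3 {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} "
                         f"{radius:.4f} {pid}")
            pid = next_id
            next_id += 1
        if level <= depth and rng.random() < branch_prob:
            axis = rng.normal(size=3)
            axis -= axis @ direction * direction
            axis /= np.linalg.norm(axis)
            ang = np.radians(35.0)
            for sgn in (1.0, -1.0):
                d2 = np.cos(ang) * direction + np.sin(ang) * sgn * axis
                grow(pid, pos, d2, radius * taper, level + 1)

    start = np.array([soma_radius, 0.0, 0.0])
    lines.append(f"2 3 {start[0]:.4f} 0.0000 0.0000 1.0000 1")
    grow(2, start, np.array([1.0, 0.0, 0.0]), 1.0, 1)
    return "\n".join(lines) + "\n"


def make_vessel_graph(seed: int = 0, n_loops: int = 1, loop_radius: float = 5.0,
                      vessel_radius: float = 0.8, n_arc: int = 12) -> str:
    """Vascular SWC with exactly ``n_loops`` independent cycles.

    Each loop is a ring of samples whose last record repeats the first
    ring sample's coordinates — the coordinate-merge convention that
    encodes cycles in the single-parent SWC column layout.  Loops are
    chained by straight bridge segments so the network is connected.
    """
    rng = np.random.default_rng(seed)
    lines = ["# synthetic vascular network"]
    next_id = 1
    prev_anchor = None
    for li in range(n_loops):
        cx = li * (2.5 * loop_radius)
        first_of_loop = None
        first_pos = None
        pid = -1
        if prev_anchor is not None:
            # bridge from previous loop
            ax, aid = prev_anchor
            bx = np.array([cx - loop_radius, 0.0, 0.0])
            mid = (ax + bx) / 2.0
            lines.append(f"{next_id} 2 {mid[0]:.4f} {mid[1]:.4f} {mid[2]:.4f} "
                         f"{vessel_radius:.4f} {aid}")
            pid = next_id
            next_id += 1
        for k in range(n_arc):
            ang = 2 * np.pi * k / n_arc
            p = np.array([cx + loop_radius * np.cos(ang),
                          loop_radius * np.sin(ang), 0.0])
            lines.append(f"{next_id} 2 {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} "
                         f"{vessel_radius:.4f} {pid}")
            if first_of_loop is None:
                first_of_loop = next_id
                first_pos = p
            pid = next_id
            next_id += 1
        # close the loop: repeat the first ring sample's coordinates
        lines.append(f"{next_id} 2 {first_pos[0]:.4f} {first_pos[1]:.4f} "
                     f"{first_pos[2]:.4f} {vessel_radius:.4f} {pid}")
        next_id += 1
        prev_anchor = (np.array([cx + loop_radius, 0.0, 0.0]), first_of_loop)
    return "\n".join(lines) + "\n"


def make_astrocyte(seed: int = 0, n_endfeet: int = 2):
    """Astrocyte fixture: (SWC text, endfeet sidecar dict).

    The skeleton is a small process tree; each endfoot is a triangle
    patch anchored at a terminal process sample (so the rasterized patch
    merges with the membrane), with uniform per-vertex thickness.
    """
    swc = make_neuron_swc(seed=seed, depth=2, branch_prob=1.0, taper=0.85,
                          soma_radius=2.5, section_length=5.0)
    # terminal samples: ids never referenced as a parent
    records = {}
    parents = set()
    for line in swc.splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        sid, stype = int(parts[0]), int(parts[1])
        if stype != 1:
            records[sid] = np.array([float(v) for v in parts[2:5]])
        parents.add(int(parts[6]))
    tips = [records[sid] for sid in sorted(records) if sid not in parents]
    rng = np.random.default_rng(seed + 1)
    endfeet = []
    for k in range(n_endfeet):
        base = tips[k % len(tips)]
        u = rng.normal(size=3); u /= np.linalg.norm(u)
        v = rng.normal(size=3); v -= v @ u * u; v /= np.linalg.norm(v)
        verts = [base, base + 2.0 * u, base + 2.0 * v, base + 2.0 * (u + v)]
        endfeet.append({
            "vertices": [list(map(float, p)) for p in verts],
            "thickness": [1.0, 1.0, 1.0, 1.0],
            "triangles": [[0, 1, 2], [1, 3, 2]],
        })
    return swc, {"endfeet": endfeet}


def standard_battery(seed: int = 0):
    """The full defect battery: named inputs for every pipeline.

    Returns a list of ``(name, pipeline, payload)`` entries, where
    ``pipeline`` names one of the eight entry points and ``payload`` holds
    the prepared inputs.  Every generator call is seeded from ``seed`` so
    the battery is reproducible; the defect classes mirror what segmented
    EM meshes exhibit: deleted faces, duplicate faces, jittered corners,
    overlapping shifted partitions, punctures, plus skeletons and masks.
    """
    import json as _json

    entries = []
    sphere = make_icosphere(2.0, 3)
    torus = make_torus(2.0, 0.7, 40, 20)

    for k in range(4):
        entries.append((f"broken_sphere_{k}", "mesh2mesh", {
            "mesh": break_mesh(sphere, seed=seed + k, del_frac=0.05,
                               dup_frac=0.05, jitter=1e-3)}))
    for k in range(2):
        entries.append((f"overlapping_partitions_{k}", "mesh2mesh", {
            "mesh": break_mesh(sphere, seed=seed + 10 + k, del_frac=0.02,
                               n_shift_partitions=1)}))
    for k in range(2):
        entries.append((f"broken_torus_{k}", "mesh2mesh", {
            "mesh": break_mesh(torus, seed=seed + 20 + k, del_frac=0.04,
                               dup_frac=0.04),
            "solid_mode": "three_way"}))
    keep = sphere.vertices[sphere.triangles].mean(axis=1)[:, 0] < 1.95
    entries.append(("punctured_sphere", "mesh2mesh", {
        "mesh": SurfaceMesh(sphere.vertices, sphere.triangles[keep]),
        "solid_mode": "three_way"}))
    entries.append(("box", "mesh2mesh", {"mesh": make_box((3.0, 2.0, 2.5))}))
    entries.append(("clean_sphere", "mesh2mesh", {"mesh": sphere}))
    a, b = sphere, make_icosphere(2.0, 3, center=(1.5, 0.3, 0.1))
    soup = SurfaceMesh(np.vstack([a.vertices, b.vertices]),
                       np.vstack([a.triangles, b.triangles + a.n_vertices]))
    entries.append(("two_sphere_soup", "mesh2mesh", {
        "mesh": break_mesh(soup, seed=seed + 30, del_frac=0.05, dup_frac=0.05)}))

    trio = [make_icosphere(1.8, 2)] + [
        make_icosphere(1.0, 2, center=(1.6 * np.cos(ang), 1.6 * np.sin(ang), 0))
        for ang in (0.0, 2.1, 4.2)]
    entries.append(("merged_group", "meshes2mesh", {"meshes": trio}))
    entries.append(("disjoint_group", "meshes2mesh", {
        "meshes": [make_icosphere(1.5, 2),
                   make_icosphere(1.0, 2, center=(7.0, 0, 0))],
        "partition_policy": "all"}))
    entries.append(("single_in_group", "meshes2mesh", {
        "meshes": [make_icosphere(1.5, 2)]}))

    ramp = np.zeros((24, 16, 16), dtype=np.uint8)
    ramp[6:14] = 120
    entries.append(("grayscale_slab", "volume2mesh", {
        "labels": ramp, "iso_range": (100, 150)}))
    grad = (np.indices((20, 20, 20)).sum(axis=0) * 4).astype(np.uint8)
    entries.append(("grayscale_gradient_band", "volume2mesh", {
        "labels": grad, "iso_range": (60, 160)}))

    entries.append(("ball_mask_small", "mask2mesh", {"mask": make_ball_mask(6)}))
    entries.append(("ball_mask_large", "mask2mesh", {"mask": make_ball_mask(10)}))
    hollow = make_ball_mask(9)
    core = make_ball_mask(5, hollow.spec.dims)
    hollow.data &= ~core.data
    entries.append(("hollow_shell_mask", "mask2mesh", {"mask": hollow}))

    for k, depth in ((0, 1), (1, 2), (2, 2), (3, 1)):
        entries.append((f"neuron_{k}", "neuro2mesh", {
            "swc": make_neuron_swc(seed=seed + 40 + k, depth=depth)}))
    for k in range(2):
        swc, ef = make_astrocyte(seed=seed + 50 + k, n_endfeet=2)
        entries.append((f"astrocyte_{k}", "astro2mesh", {
            "swc": swc, "endfeet": _json.dumps(ef)}))
    entries.append(("vessel_ring", "vess2mesh", {
        "swc": make_vessel_graph(seed=seed + 60, n_loops=1)}))
    entries.append(("vessel_two_loops", "vess2mesh", {
        "swc": make_vessel_graph(seed=seed + 61, n_loops=2)}))
    entries.append(("vessel_ring_alt", "vess2mesh", {
        "swc": make_vessel_graph(seed=seed + 62, n_loops=1, loop_radius=4.0)}))

    entries.append(("single_tet", "tet2surface", {
        "vertices": [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        "tets": [[0, 1, 2, 3]]}))
    cube_v = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
    entries.append(("cube_tets", "tet2surface", {
        "vertices": cube_v,
        "tets": [[0, 1, 2, 4], [1, 2, 3, 7], [1, 4, 5, 7], [2, 4, 6, 7],
                 [1, 2, 4, 7]]}))
    return entries


def make_ball_mask(radius_voxels: float, dims=None, voxel_size: float = 1.0,
                   origin=(0.0, 0.0, 0.0)) -> BitVolumeGrid:
    """Solid lattice ball: voxel set ⇔ its center is within the radius of
    the grid center.  Radius 0 sets exactly the central voxel."""
    if dims is None:
        n = int(2 * np.ceil(radius_voxels) + 5)
        dims = (n, n, n)
    spec = GridSpec(tuple(origin), voxel_size, dims)
    idx = np.indices(dims).astype(float)
    center = (np.asarray(dims) - 1) / 2.0
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return BitVolumeGrid(spec, d2 <= radius_voxels ** 2 + 1e-9)
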
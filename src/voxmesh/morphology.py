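"""Morphology skeletons and their conversion to rasterizable proxy geometry.

A morphology is a graph of samples — 3D position plus cross-sectional
radius — organized into *sections*: maximal unbranched chains between
branching or terminal nodes.  Neurons and astrocytes are rooted acyclic
trees with a soma; vascular networks may be cyclic and multi-component.

Proxy geometry is disposable: the tubes, spheres and soma surfaces built
here may interpenetrate freely, because their only contract is faithful
conservative rasterization into a voxel grid.  Watertightness is
established downstream from the voxelized solid, never from the proxies.

Two proxy strategies exist.  Per-path proxies sweep tubes along every
root-to-leaf path (depth-first enumeration), which guarantees smooth,
gap-free bifurcation geometry on acyclic trees.  Per-section proxies
sweep one tube per section and add a packing sphere at every branch
point — radius equal to the largest terminal-sample radius of the
sections meeting there — which also works on cyclic vascular graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt

from .mesh_core import SurfaceMesh

__all__ = [
    "Sample",
    "Section",
    "Soma",
    "EndfootPatch",
    "Morphology",
    "MorphologyStructureError",
    "repair_skeleton",
    "resample_adaptive",
    "catmull_rom_tangents",
    "interpolate_path",
    "sweep_tube",
    "build_paths",
    "per_section_proxies",
    "per_path_proxies",
    "make_icosphere_mesh",
    "reconstruct_soma",
    "endfeet_proxy",
    "neurite_connectivity",
]


class MorphologyStructureError(ValueError):
    """Structural defect: cycle in a neuron, orphan section, empty section."""


@dataclass
class Sample:
    position: np.ndarray
    radius: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.radius = float(self.radius)
        if self.radius < 0:
            raise ValueError("sample radius must be >= 0")


@dataclass
class Section:
    """Maximal unbranched chain of samples; adjacent samples form segments."""

    id: int
    samples: list[Sample]
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.position for s in self.samples])

    @property
    def radii(self) -> np.ndarray:
        return np.asarray([s.radius for s in self.samples])


@dataclass
class Soma:
    centroid: np.ndarray
    mean_radius: float
    root_sections: list[int] = field(default_factory=list)


@dataclass
class EndfootPatch:
    """Astrocytic endfoot: triangle patch with per-vertex thickness (μm)."""

    vertices: np.ndarray        # (n, 3)
    thickness: np.ndarray       # (n,)
    triangles: np.ndarray       # (m, 3)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.thickness = np.asarray(self.thickness, dtype=float).reshape(-1)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.thickness) != len(self.vertices):
            raise ValueError("one thickness per vertex required")
        if np.any(self.thickness <= 0):
            raise ValueError("endfoot thickness must be > 0")
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise ValueError("endfoot triangle indices out of range")


@dataclass
class Morphology:
    sections: dict[int, Section]
    kind: str = "neuron"                      # neuron | astrocyte | vasculature
    soma: Soma | None = None
    endfeet: list[EndfootPatch] = field(default_factory=list)

    def root_ids(self) -> list[int]:
        return sorted(s.id for s in self.sections.values() if s.parent is None)

    def all_sample_positions(self) -> np.ndarray:
        pts = [sec.positions for sec in self.sections.values()]
        return np.vstack(pts) if pts else np.empty((0, 3))


# ---------------------------------------------------------------------------
# skeleton repair and resampling

def repair_skeleton(m: Morphology) -> Morphology:
    """Fix degenerate samples in place-preserving copies of every section.

    Zero/near-zero radii are linearly interpolated from the nearest valid
    neighbors along the section; coincident consecutive samples are
    merged; radius sequences of sections with ≥5 samples are median
    filtered (window 3) to remove single-sample spikes.
    """
    out = {}
    for sid, sec in m.sections.items():
        pos = sec.positions
        rad = sec.radii.copy()
        # merge zero-length segments
        keep = np.ones(len(pos), dtype=bool)
        for i in range(1, len(pos)):
            prev = np.flatnonzero(keep[:i])[-1]
            if np.linalg.norm(pos[i] - pos[prev]) < 1e-9:
                keep[i] = False
                rad[prev] = max(rad[prev], rad[i])
        pos, rad = pos[keep], rad[keep]
        if len(pos) < 2:
            raise MorphologyStructureError(
                f"section {sid} reduced to {len(pos)} sample(s) after merging")
        rad = _interp_invalid_radii(pos, rad, sid)
        if len(rad) >= 5:
            filt = medfilt(rad, kernel_size=3)
            filt[0], filt[-1] = rad[0], rad[-1]   # endpoints untouched
            rad = filt
        out[sid] = Section(sid, [Sample(p, r) for p, r in zip(pos, rad)],
                           sec.parent, list(sec.children))
    return Morphology(out, m.kind, m.soma, list(m.endfeet))


def _interp_invalid_radii(pos: np.ndarray, rad: np.ndarray, sid: int,
                          tiny: float = 1e-6) -> np.ndarray:
    bad = rad <= tiny
    if not bad.any():
        return rad
    if bad.all():
        raise MorphologyStructureError(
            f"section {sid} has no valid radius to interpolate from")
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pos, axis=0), axis=1))])
    good = ~bad
    return np.interp(arc, arc[good], rad[good])


def resample_adaptive(section: Section) -> Section:
    """Greedy sparsification: keep a sample only when it is farther from
    the last kept sample than that kept sample's radius; endpoints always
    kept.  Kept samples are never moved."""
    samples = section.samples
    if len(samples) <= 2:
        return Section(section.id, list(samples), section.parent,
                       list(section.children))
    kept = [samples[0]]
    for s in samples[1:-1]:
        if np.linalg.norm(s.position - kept[-1].position) > kept[-1].radius:
            kept.append(s)
    kept.append(samples[-1])
    return Section(section.id, kept, section.parent, list(section.children))


# ---------------------------------------------------------------------------
# spline interpolation

def catmull_rom_tangents(knots: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Tangents and knot parameters of the centripetal Catmull–Rom spline.

    Knot parameters accumulate as ``t_{j+1} = t_j + |p_{j+1}-p_j|^α``
    (α = 0.5); interior tangents use the non-uniform three-point formula
    on the previous and next knots, endpoints one-sided differences.
    Returns ``(tangents (n,3), t (n,))``.
    """
    p = np.asarray(knots, dtype=float)
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 knots")
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    dt = np.maximum(d, 1e-12) ** alpha
    t = np.concatenate([[0.0], np.cumsum(dt)])
    tan = np.empty_like(p)
    tan[0] = (p[1] - p[0]) / dt[0]
    tan[-1] = (p[-1] - p[-2]) / dt[-1]
    for i in range(1, n - 1):
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        # standard non-uniform Catmull–Rom tangent (previous and next knots)
        tan[i] = ((p[i] - p[i - 1]) / (t1 - t0)
                  + (p[i + 1] - p[i]) / (t2 - t1)
                  - (p[i + 1] - p[i - 1]) / (t2 - t0))
    return tan, t


def _hermite(p0, p1, m0, m1, dt, u):
    """Cubic Hermite on one segment; u in [0,1], tangents in t-parameter units."""
    u = np.asarray(u, dtype=float)[:, None]
    h00 = 2 * u ** 3 - 3 * u ** 2 + 1
    h10 = u ** 3 - 2 * u ** 2 + u
    h01 = -2 * u ** 3 + 3 * u ** 2
    h11 = u ** 3 - u ** 2
    return h00 * p0 + h10 * (dt * m0) + h01 * p1 + h11 * (dt * m1)


def interpolate_path(samples: list[Sample], step: float) -> list[Sample]:
    """Resample a polyline of samples with cubic Hermite segments.

    Tangents come from the centripetal Catmull–Rom formulation using the
    previous and next samples (one-sided at the endpoints); radii are
    linearly interpolated along arc length; output spacing ≤ ``step``.
    Original sample positions are reproduced exactly at segment ends.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to interpolate")
    pos = np.asarray([s.position for s in samples])
    rad = np.asarray([s.radius for s in samples])
    if step <= 0:
        raise ValueError("step must be > 0")
    tan, t = catmull_rom_tangents(pos)
    out_pos = [pos[0]]
    out_rad = [rad[0]]
    for i in range(len(pos) - 1):
        seg_len = np.linalg.norm(pos[i + 1] - pos[i])
        n_sub = max(1, int(np.ceil(seg_len / step)))
        u = np.arange(1, n_sub + 1) / n_sub
        dt = t[i + 1] - t[i]
        pts = _hermite(pos[i], pos[i + 1], tan[i], tan[i + 1], dt, u)
        rr = rad[i] + (rad[i + 1] - rad[i]) * u
        out_pos.extend(pts)
        out_rad.extend(rr)
    return [Sample(p, r) for p, r in zip(out_pos, out_rad)]


# ---------------------------------------------------------------------------
# tube sweeping

def _parallel_transport_frames(points: np.ndarray) -> np.ndarray:
    """Twist-free orthonormal frames (n, 2, 3) normal to the local tangent."""
    n = len(points)
    tangents = np.empty((n, 3))
    tangents[0] = points[1] - points[0]
    tangents[-1] = points[-1] - points[-2]
    if n > 2:
        tangents[1:-1] = points[2:] - points[:-2]
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents = np.divide(tangents, norms, out=np.tile(np.array([[1.0, 0, 0]]), (n, 1)),
                         where=norms > 1e-12)
    # initial normal: any vector not parallel to the first tangent
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0]) if abs(t0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t0, ref)
    u /= np.linalg.norm(u)
    frames = np.empty((n, 2, 3))
    for i in range(n):
        ti = tangents[i]
        if i > 0:
            # rotate previous frame by the rotation taking t_{i-1} to t_i
            tp = tangents[i - 1]
            axis = np.cross(tp, ti)
            s = np.linalg.norm(axis)
            c = float(np.clip(tp @ ti, -1.0, 1.0))
            if s > 1e-12:
                axis = axis / s
                ang = np.arctan2(s, c)
                u = _rotate(u, axis, ang)
            elif c < 0:
                u = -u
        u = u - (u @ ti) * ti
        u /= np.linalg.norm(u)
        frames[i, 0] = u
        frames[i, 1] = np.cross(ti, u)
    return frames


def _rotate(vec, axis, angle):
    c, s = np.cos(angle), np.sin(angle)
    return (vec * c + np.cross(axis, vec) * s + axis * (axis @ vec) * (1 - c))


def sweep_tube(path: list[Sample], n_ring: int = 16) -> SurfaceMesh:
    """Sweep a circular cross-section along a path of samples.

    One ring of ``n_ring`` vertices per path point, lying in the plane
    whose normal is the local tangent, radius equal to the sample radius;
    frames are parallel-transported so the tube never twists.  Consecutive
    rings are stitched with 2·n_ring triangles and the ends are capped
    with fans around apex vertices.
    """
    if n_ring < 3:
        raise ValueError("n_ring must be >= 3")
    if len(path) < 2:
        raise ValueError("path needs at least 2 samples")
    pts = np.asarray([s.position for s in path])
    radii = np.asarray([max(s.radius, 1e-9) for s in path])
    frames = _parallel_transport_frames(pts)
    theta = 2 * np.pi * np.arange(n_ring) / n_ring
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rings = (pts[:, None, :]
             + radii[:, None, None] * (cos_t[None, :, None] * frames[:, None, 0]
                                       + sin_t[None, :, None] * frames[:, None, 1]))
    n_pts = len(pts)
    verts = rings.reshape(-1, 3)
    tris = []
    for i in range(n_pts - 1):
        base0, base1 = i * n_ring, (i + 1) * n_ring
        for k in range(n_ring):
            k2 = (k + 1) % n_ring
            tris.append((base0 + k, base1 + k, base1 + k2))
            tris.append((base0 + k, base1 + k2, base0 + k2))
    # end caps: fan around apex at path endpoints
    verts = np.vstack([verts, pts[0], pts[-1]])
    a0, a1 = len(verts) - 2, len(verts) - 1
    for k in range(n_ring):
        k2 = (k + 1) % n_ring
        tris.append((a0, k2, k))
        base = (n_pts - 1) * n_ring
        tris.append((a1, base + k, base + k2))
    return SurfaceMesh(verts, np.asarray(tris, dtype=np.int64))


# ---------------------------------------------------------------------------
# path enumeration and proxies

def build_paths(m: Morphology) -> list[list[Sample]]:
    """Depth-first enumeration of all root-to-leaf sample paths.

    Every (parent, child) section adjacency appears in at least one path
    and every root-to-leaf route exactly once.  When a soma is present,
    paths are prepended with a sample at the soma centroid so proxies
    start from the soma origin and leave no gaps.
    """
    if m.kind == "vasculature":
        raise MorphologyStructureError(
            "path enumeration requires an acyclic morphology; use "
            "per-section proxies for vascular graphs")
    paths: list[list[Sample]] = []
    soma_reachable = _soma_descendants(m)
    for root in m.root_ids():
        stack = [(root, [])]
        while stack:
            sid, prefix = stack.pop()
            if sid in prefix:
                raise MorphologyStructureError(f"cycle through section {sid}")
            chain = prefix + [sid]
            sec = m.sections[sid]
            if not sec.children:
                samples: list[Sample] = []
                for cid in chain:
                    ss = m.sections[cid].samples
                    samples.extend(ss if not samples else ss[1:])
                if m.soma is not None and sid in soma_reachable:
                    samples = [Sample(m.soma.centroid, samples[0].radius)] + samples
                paths.append(samples)
            else:
                for cid in sorted(sec.children, reverse=True):
                    stack.append((cid, chain))
    return paths


def _soma_descendants(m: Morphology) -> set[int]:
    if m.soma is None:
        return set()
    out = set()
    stack = list(m.soma.root_sections)
    while stack:
        sid = stack.pop()
        if sid in out:
            continue
        out.add(sid)
        stack.extend(m.sections[sid].children)
    return out


def per_path_proxies(m: Morphology, n_ring: int = 16,
                     step: float | None = None) -> list[SurfaceMesh]:
    """One swept tube per root-to-leaf path (acyclic morphologies)."""
    out = []
    for path in build_paths(m):
        h = step if step is not None else max(min(s.radius for s in path), 1e-3)
        dense = interpolate_path(path, h)
        out.append(sweep_tube(dense, n_ring))
    return out


def per_section_proxies(m: Morphology, n_ring: int = 16,
                        step: float | None = None) -> list[SurfaceMesh]:
    """One swept tube per section plus a packing icosphere per branch point.

    The sphere radius is the maximum terminal-sample radius over all
    sections meeting at the point; works on cyclic vascular graphs.
    """
    out = []
    # gather branch points: section endpoints shared by >= 2 sections
    endpoint_map: dict[tuple, list[float]] = {}
    for sec in m.sections.values():
        h = step if step is not None else max(min(sec.radii), 1e-3)
        dense = interpolate_path(sec.samples, h)
        out.append(sweep_tube(dense, n_ring))
        for s in (sec.samples[0], sec.samples[-1]):
            key = tuple(np.round(s.position, 9))
            endpoint_map.setdefault(key, []).append(s.radius)
    for key, radii in endpoint_map.items():
        if len(radii) >= 2:
            out.append(make_icosphere_mesh(max(radii), 2, center=np.asarray(key)))
    return out


def branch_point_radii(m: Morphology) -> dict[tuple, float]:
    """Packing-sphere radii keyed by branch-point position."""
    endpoint_map: dict[tuple, list[float]] = {}
    for sec in m.sections.values():
        for s in (sec.samples[0], sec.samples[-1]):
            key = tuple(np.round(s.position, 9))
            endpoint_map.setdefault(key, []).append(s.radius)
    return {k: max(v) for k, v in endpoint_map.items() if len(v) >= 2}


# ---------------------------------------------------------------------------
# icosphere (local copy to keep morphology self-contained for proxies)

def make_icosphere_mesh(radius: float, subdivisions: int = 3,
                        center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Geodesic icosphere: subdivided icosahedron projected to the sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([[-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
                  [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
                  [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]],
                 dtype=float)
    v /= np.linalg.norm(v[0])
    t = np.array([[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
                  [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
                  [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
                  [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]],
                 dtype=np.int64)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        verts = list(v)

        def midpoint(a, b):
            key = (a, b) if a < b else (b, a)
            got = cache.get(key)
            if got is not None:
                return got
            p = (verts[a] + verts[b]) / 2.0
            p = p / np.linalg.norm(p)
            verts.append(p)
            cache[key] = len(verts) - 1
            return cache[key]

        new_t = []
        for a, b, c in t:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_t += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        v = np.asarray(verts)
        t = np.asarray(new_t, dtype=np.int64)
    return SurfaceMesh(v * radius + np.asarray(center, dtype=float), t)


# ---------------------------------------------------------------------------
# soma reconstruction

def reconstruct_soma(m: Morphology, pull_steps: int = 10,
                     subdivisions: int = 3) -> SurfaceMesh:
    """Deformable-icosphere soma surrogate.

    Starts from a subdivided icosphere at the soma centroid with the mean
    soma radius.  For every soma-connected neurite, the vertex cluster
    inside the spherical cap facing the neurite's initial segment (angular
    radius ``asin(min(1, r_seg / r_soma))``) is pulled toward that segment
    in ``pull_steps`` increments until the cluster centroid reaches it.
    A final uniform scale about the centroid restores the initial enclosed
    volume to within 1%.
    """
    if m.soma is None:
        raise MorphologyStructureError("morphology has no soma")
    from .mesh_core import enclosed_volume

    soma = m.soma
    sphere = make_icosphere_mesh(soma.mean_radius, subdivisions, soma.centroid)
    v0 = enclosed_volume(sphere)
    if not soma.root_sections:
        warnings.warn("soma has no connected neurites; returning plain icosphere")
        return sphere
    verts = sphere.vertices.copy()
    c = np.asarray(soma.centroid, dtype=float)
    for sid in soma.root_sections:
        sec = m.sections.get(sid)
        if sec is None:
            continue
        target = sec.samples[0].position
        r_seg = max(sec.samples[0].radius, 1e-6)
        direction = target - c
        dist = np.linalg.norm(direction)
        if dist < 1e-9:
            continue
        direction = direction / dist
        cap_angle = np.arcsin(min(1.0, r_seg / max(soma.mean_radius, 1e-9)))
        rel = verts - c
        rn = np.linalg.norm(rel, axis=1)
        cosang = (rel @ direction) / np.maximum(rn, 1e-12)
        cluster = cosang >= np.cos(cap_angle)
        if not cluster.any():
            cluster = cosang >= np.partition(cosang, -3)[-3]  # ≥3 nearest vertices
        for _ in range(pull_steps):
            centroid = verts[cluster].mean(axis=0)
            gap = target - centroid
            if np.linalg.norm(gap) < 1e-9:
                break
            verts[cluster] += gap / pull_steps
        # final snap so the cluster centroid reaches the initial segment
        verts[cluster] += target - verts[cluster].mean(axis=0)
    bulged = SurfaceMesh(verts, sphere.triangles.copy())
    v1 = enclosed_volume(bulged)
    scale = (v0 / v1) ** (1.0 / 3.0)
    verts = c + (verts - c) * scale
    return SurfaceMesh(verts, sphere.triangles.copy())


# ---------------------------------------------------------------------------
# endfeet

def endfeet_proxy(patches: list[EndfootPatch], grid) -> None:
    """Rasterize endfoot patches into ``grid`` as unions of spheres.

    Patch edges longer than the local thickness are midpoint-subdivided
    (thickness averaged) until compliant; a sphere of radius thickness/2
    is stamped at every vertex and at points spaced ≤ voxel_size/2 along
    every edge, giving a 26-connected shell whenever thickness ≥ 2·voxel.
    """
    h = grid.spec.voxel_size
    for patch in patches:
        verts, thick, tris = _subdivide_patch(patch)
        _stamp_spheres(grid, verts, thick / 2.0)
        edges = set()
        for t in tris:
            for i in range(3):
                a, b = int(t[i]), int(t[(i + 1) % 3])
                edges.add((min(a, b), max(a, b)))
        for a, b in edges:
            seg = verts[b] - verts[a]
            length = np.linalg.norm(seg)
            n_sub = max(1, int(np.ceil(length / (h / 2.0))))
            u = np.arange(1, n_sub)[:, None] / n_sub
            pts = verts[a] + u * seg
            rr = (thick[a] + (thick[b] - thick[a]) * u[:, 0]) / 2.0
            _stamp_spheres(grid, pts, rr)


def _subdivide_patch(patch: EndfootPatch, max_gen: int = 24):
    verts = list(patch.vertices)
    thick = list(patch.thickness)
    tris = [tuple(int(x) for x in t) for t in patch.triangles]
    for _ in range(max_gen):
        new_tris = []
        changed = False
        for t in tris:
            # split the longest edge exceeding the local thickness
            split = None
            worst = 0.0
            for i in range(3):
                a, b = t[i], t[(i + 1) % 3]
                limit = min(thick[a], thick[b])
                length = float(np.linalg.norm(np.asarray(verts[a]) - verts[b]))
                if length > limit and length > worst:
                    split = (i, a, b)
                    worst = length
            if split is None:
                new_tris.append(t)
                continue
            changed = True
            i, a, b = split
            c = t[(i + 2) % 3]
            verts.append((np.asarray(verts[a]) + verts[b]) / 2.0)
            thick.append((thick[a] + thick[b]) / 2.0)
            mi = len(verts) - 1
            new_tris += [(a, mi, c), (mi, b, c)]
        tris = new_tris
        if not changed:
            break
    return np.asarray(verts), np.asarray(thick), tris


def _stamp_spheres(grid, centers: np.ndarray, radii) -> None:
    """Set all voxels whose center lies within radius of each center."""
    spec = grid.spec
    h = spec.voxel_size
    origin = np.asarray(spec.origin)
    dims = np.asarray(spec.dims)
    centers = np.atleast_2d(centers)
    radii = np.broadcast_to(np.asarray(radii, dtype=float).reshape(-1), (len(centers),))
    for ctr, r in zip(centers, radii):
        r_eff = max(r, 0.5 * h)       # always mark at least the host voxel
        lo = np.maximum(np.floor((ctr - r_eff - origin) / h).astype(int), 0)
        hi = np.minimum(np.floor((ctr + r_eff - origin) / h).astype(int), dims - 1)
        if np.any(hi < lo):
            continue
        xs = np.arange(lo[0], hi[0] + 1)
        ys = np.arange(lo[1], hi[1] + 1)
        zs = np.arange(lo[2], hi[2] + 1)
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        cx = origin[0] + (gx + 0.5) * h
        cy = origin[1] + (gy + 0.5) * h
        cz = origin[2] + (gz + 0.5) * h
        mask = ((cx - ctr[0]) ** 2 + (cy - ctr[1]) ** 2 + (cz - ctr[2]) ** 2
                <= r_eff ** 2 + 1e-12)
        grid.data[gx[mask], gy[mask], gz[mask]] = True


# ---------------------------------------------------------------------------
# soma connectivity

def neurite_connectivity(m: Morphology, k: float = 2.0):
    """Classify root sections as soma-connected or detached.

    A root is connected when its first sample lies within ``k`` mean soma
    radii of the soma centroid; detached roots are bridged to the centroid
    by a straight two-sample proxy segment.

    Returns (connected_ids, bridges) where bridges is a list of
    (section_id, [Sample, Sample]) straight segments.
    """
    if m.soma is None or m.soma.mean_radius <= 0:
        warnings.warn("no soma defined; bridging every root to the mean position")
        pts = m.all_sample_positions()
        centroid = pts.mean(axis=0) if len(pts) else np.zeros(3)
        radius = 0.0
    else:
        centroid = np.asarray(m.soma.centroid)
        radius = m.soma.mean_radius
    connected, bridges = [], []
    for rid in m.root_ids():
        first = m.sections[rid].samples[0]
        if radius > 0 and np.linalg.norm(first.position - centroid) <= k * radius:
            connected.append(rid)
        else:
            bridges.append((rid, [Sample(centroid, first.radius), first]))
    return connected, bridges
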
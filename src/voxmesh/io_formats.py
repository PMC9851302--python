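"""File readers and writers: surface meshes, SWC skeletons, mask stacks.

Mesh interchange (OBJ, PLY ascii/binary, OFF, STL ascii/binary) is
delegated to ``trimesh``; polygonal faces with more than three vertices
are triangulated on load.  SWC is parsed here: one whitespace-separated
record per line — id, type, x, y, z, radius, parent — with ``#``
comments.  Binary mask stacks are read with ``tifffile``.

SWC conventions
---------------
* Neuron/astrocyte kind builds a rooted tree.  Contiguous type-1 samples
  form the soma; the soma centroid is their mean position and the mean
  soma radius is the mean distance from the centroid to the first sample
  of each root-attached neurite (falling back to the type-1 radius when
  no neurites exist).
* Vasculature kind builds a general graph: samples at identical
  coordinates are merged into a single node, which is how closed loops
  are encoded in a single-parent format; multiple roots are permitted.
  The same coincidence closing a loop in neuron kind is a cycle error.
* Sections are maximal unbranched chains between branching/terminal nodes.
"""

from __future__ import annotations

import json
import os


import numpy as np
import trimesh

from .mesh_core import SurfaceMesh, triangulate_ngons
from .morphology import EndfootPatch, Morphology, Sample, Section, Soma
from .volume_grid import BitVolumeGrid, GridSpec

__all__ = [
    "MeshFormatError",
    "SwcFormatError",
    "read_mesh",
    "write_mesh",
    "read_swc",
    "write_swc",
    "read_endfeet_json",
    "write_endfeet_json",
    "read_mask_stack",
]

_MESH_EXTS = {".obj": "obj", ".ply": "ply", ".off": "off", ".stl": "stl"}


class MeshFormatError(ValueError):
    pass


class SwcFormatError(ValueError):
    pass


def _format_of(path: str, format: str | None) -> str:
    if format:
        return format.lower()
    ext = os.path.splitext(path)[1].lower()
    if ext not in _MESH_EXTS:
        raise MeshFormatError(f"unknown mesh extension {ext!r} for {path}")
    return _MESH_EXTS[ext]


def read_mesh(path: str, format: str | None = None) -> SurfaceMesh:
    """Load a surface mesh; n-gon faces are triangulated."""
    fmt = _format_of(path, format)
    try:
        loaded = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    faces = np.asarray(loaded.faces)
    if faces.ndim == 2 and faces.shape[1] > 3:
        faces = triangulate_ngons(faces)
    return SurfaceMesh(np.asarray(loaded.vertices, dtype=float), faces)


def write_mesh(mesh: SurfaceMesh, path: str, format: str | None = None) -> None:
    fmt = _format_of(path, format)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    tm.export(path, file_type=fmt)


# ---------------------------------------------------------------------------
# SWC

def _parse_swc_records(path: str, radius_is_diameter: bool = False):
    records = {}
    order = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 7:
                raise SwcFormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                sid = int(parts[0]); stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcFormatError(f"{path}:{lineno}: non-numeric field "
                                     f"({exc})") from exc
            if radius_is_diameter:
                r /= 2.0
            if sid in records:
                raise SwcFormatError(f"{path}:{lineno}: duplicate id {sid}")
            if parent != -1 and parent not in records:
                raise SwcFormatError(
                    f"{path}:{lineno}: parent {parent} of sample {sid} not "
                    "yet defined (forward references rejected)")
            if r < 0:
                raise SwcFormatError(f"{path}:{lineno}: negative radius")
            records[sid] = (stype, np.array([x, y, z]), r, parent)
            order.append(sid)
    if not records:
        raise SwcFormatError(f"{path}: no samples")
    return records, order


def read_swc(path: str, kind: str = "neuron",
             radius_is_diameter: bool = False) -> Morphology:
    """Parse an SWC file into a :class:`Morphology` of the given kind."""
    if kind not in ("neuron", "astrocyte", "vasculature"):
        raise ValueError(f"unknown morphology kind {kind!r}")
    records, order = _parse_swc_records(path, radius_is_diameter)
    if kind == "vasculature":
        return _swc_to_graph(records, order, path)
    return _swc_to_tree(records, order, kind, path)


def _node_key(pos: np.ndarray) -> tuple:
    return tuple(np.round(pos, 9))


def _swc_to_tree(records, order, kind, path) -> Morphology:
    soma_ids = [sid for sid in order if records[sid][0] == 1]
    neurite_ids = [sid for sid in order if records[sid][0] != 1]
    # cycle detection via coincident-coordinate merging
    seen_keys: dict[tuple, int] = {}
    children: dict[int, list[int]] = {sid: [] for sid in order}
    for sid in neurite_ids:
        stype, pos, r, parent = records[sid]
        key = _node_key(pos)
        if key in seen_keys:
            other = seen_keys[key]
            # coincident with an earlier sample that is not its parent → loop
            if other != parent and records[sid][3] != -1:
                raise SwcFormatError(
                    f"{path}: sample {sid} closes a loop at {key} with sample "
                    f"{other}; cycles are not allowed in {kind} morphologies")
        seen_keys[key] = sid
        if parent != -1 and records[parent][0] != 1:
            children[parent].append(sid)

    soma = None
    if soma_ids:
        centroid = np.mean([records[s][1] for s in soma_ids], axis=0)
        soma = Soma(centroid, float(np.mean([records[s][2] for s in soma_ids])))

    # branch nodes: >1 child, or root
    sections: dict[int, Section] = {}
    sec_of_start: dict[int, int] = {}
    next_sec = 0
    roots = [sid for sid in neurite_ids
             if records[sid][3] == -1 or records[sid][3] in soma_ids]

    def emit(chain_ids, parent_sec):
        nonlocal next_sec
        samples = [Sample(records[s][1], records[s][2]) for s in chain_ids]
        sec = Section(next_sec, samples, parent_sec)
        sections[next_sec] = sec
        if parent_sec is not None:
            sections[parent_sec].children.append(next_sec)
        next_sec += 1
        return sec.id

    # chains: child sections start at the branch sample so the branch node
    # position is shared between parent and child sections (no gaps)
    stack = [(rid, None, None) for rid in reversed(roots)]
    visited = set()
    while stack:
        start, parent_sec, branch_sample = stack.pop()
        chain = [] if branch_sample is None else [branch_sample]
        chain.append(start)
        visited.add(start)
        cur = start
        while len(children[cur]) == 1:
            nxt = children[cur][0]
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        if len(chain) < 2:
            raise SwcFormatError(
                f"{path}: root sample {start} forms a 1-sample section")
        sid = emit(chain, parent_sec)
        for child in reversed(children[cur]):
            stack.append((child, sid, cur))
    unvisited = set(neurite_ids) - visited
    if unvisited:
        raise SwcFormatError(f"{path}: unreachable samples {sorted(unvisited)[:5]}")
    morph = Morphology(sections, kind, soma)
    if soma is not None:
        morph.soma.root_sections = [s.id for s in sections.values()
                                    if s.parent is None]
        _refine_soma_radius(morph, records, soma_ids)
    return morph


def _refine_soma_radius(morph, records, soma_ids):
    """Mean radius = mean distance from centroid to first neurite samples."""
    soma = morph.soma
    firsts = [morph.sections[rid].samples[0].position
              for rid in soma.root_sections]
    if firsts:
        soma.mean_radius = float(np.mean(
            [np.linalg.norm(p - soma.centroid) for p in firsts]))
    # else: keep the type-1 radius fallback


def _swc_to_graph(records, order, path) -> Morphology:
    """Vasculature: general graph, coincident samples merged into nodes."""
    import networkx as nx

    g = nx.Graph()
    key_of: dict[int, tuple] = {}
    for sid in order:
        stype, pos, r, parent = records[sid]
        key = _node_key(pos)
        key_of[sid] = key
        if key not in g:
            g.add_node(key, radius=r, pos=pos)
        else:
            g.nodes[key]["radius"] = max(g.nodes[key]["radius"], r)
        if parent != -1:
            pk = key_of[parent]
            if pk != key:
                g.add_edge(pk, key)
    sections: dict[int, Section] = {}
    next_id = 0
    # section endpoints: nodes with degree != 2
    deg = dict(g.degree())
    used_edges = set()

    def walk(start, first):
        chain = [start, first]
        used_edges.add(frozenset((start, first)))
        cur, prev = first, start
        while deg[cur] == 2:
            nbrs = [n for n in g.neighbors(cur) if n != prev]
            if not nbrs:
                break
            nxt = nbrs[0]
            if frozenset((cur, nxt)) in used_edges:
                break
            chain.append(nxt)
            used_edges.add(frozenset((cur, nxt)))
            prev, cur = cur, nxt
        return chain

    terminals = [n for n in g.nodes if deg[n] != 2]
    for node in terminals:
        for nb in g.neighbors(node):
            if frozenset((node, nb)) in used_edges:
                continue
            chain = walk(node, nb)
            samples = [Sample(g.nodes[n]["pos"], g.nodes[n]["radius"])
                       for n in chain]
            sections[next_id] = Section(next_id, samples, None)
            next_id += 1
    # pure cycles with no terminal at all (every node degree 2)
    for comp_edges in _leftover_cycles(g, used_edges):
        samples = [Sample(g.nodes[n]["pos"], g.nodes[n]["radius"])
                   for n in comp_edges]
        sections[next_id] = Section(next_id, samples, None)
        next_id += 1
    if not sections:
        raise SwcFormatError(f"{path}: no sections recoverable from graph")
    return Morphology(sections, "vasculature")


def _leftover_cycles(g, used_edges):
    out = []
    remaining = [e for e in g.edges if frozenset(e) not in used_edges]
    seen = set()
    for a, b in remaining:
        if frozenset((a, b)) in seen:
            continue
        chain = [a, b]
        seen.add(frozenset((a, b)))
        cur, prev = b, a
        while cur != a:
            nbrs = [n for n in g.neighbors(cur)
                    if n != prev and frozenset((cur, n)) not in seen]
            if not nbrs:
                break
            nxt = nbrs[0]
            seen.add(frozenset((cur, nxt)))
            chain.append(nxt)
            prev, cur = cur, nxt
        out.append(chain)
    return out


def write_swc(morph: Morphology, path: str) -> None:
    """Write a morphology back to SWC (soma as a single type-1 sample)."""
    lines = ["# generated by voxmesh"]
    next_id = 1
    node_ids: dict[tuple, int] = {}
    if morph.soma is not None:
        c = morph.soma.centroid
        lines.append(f"1 1 {c[0]:.6f} {c[1]:.6f} {c[2]:.6f} "
                     f"{morph.soma.mean_radius:.6f} -1")
        next_id = 2
    type_code = {"neuron": 3, "astrocyte": 7, "vasculature": 2}[morph.kind]
    emitted: dict[int, int] = {}

    def emit_section(sec, parent_sample):
        nonlocal next_id
        last = parent_sample
        start = 1 if (parent_sample is not None and sec.parent is not None) else 0
        for s in sec.samples[start:]:
            key = _node_key(s.position)
            if key in node_ids:
                last = node_ids[key]
                continue
            p = s.position
            pid = last if last is not None else -1
            lines.append(f"{next_id} {type_code} {p[0]:.6f} {p[1]:.6f} "
                         f"{p[2]:.6f} {s.radius:.6f} {pid}")
            node_ids[key] = next_id
            last = next_id
            next_id += 1
        emitted[sec.id] = last

    order = sorted(morph.sections)
    for sid in order:
        sec = morph.sections[sid]
        if sec.parent is None:
            pid = 1 if morph.soma is not None else None
            emit_section(sec, pid)
    for sid in order:
        sec = morph.sections[sid]
        if sec.parent is not None:
            emit_section(sec, emitted.get(sec.parent))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# endfeet JSON sidecar

def read_endfeet_json(path: str) -> list[EndfootPatch]:
    """Endfeet sidecar schema: ``{"endfeet": [{"vertices": [[x,y,z]...],
    "thickness": [...], "triangles": [[i,j,k]...]}]}``."""
    with open(path) as fh:
        doc = json.load(fh)
    patches = []
    for i, entry in enumerate(doc.get("endfeet", [])):
        try:
            patches.append(EndfootPatch(np.asarray(entry["vertices"]),
                                        np.asarray(entry["thickness"]),
                                        np.asarray(entry["triangles"])))
        except (KeyError, ValueError) as exc:
            raise MeshFormatError(f"{path}: endfoot {i}: {exc}") from exc
    return patches


def write_endfeet_json(patches: list[EndfootPatch], path: str) -> None:
    doc = {"endfeet": [{
        "vertices": p.vertices.tolist(),
        "thickness": p.thickness.tolist(),
        "triangles": p.triangles.tolist(),
    } for p in patches]}
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# mask stacks

def read_mask_stack(source, voxel_size: float = 1.0,
                    origin=(0.0, 0.0, 0.0)) -> BitVolumeGrid:
    """Read a binary mask stack (ordered image files or one 3D TIFF).

    Pixel values are binarized at > 0.  The grid has dims
    (width, height, n_slices); masks carry no units, so ``voxel_size``
    and ``origin`` come from configuration.
    """
    import tifffile

    if isinstance(source, (str, os.PathLike)):
        arr = tifffile.imread(source)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        slices = [tifffile.imread(p) for p in source]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise MeshFormatError(f"inconsistent slice shapes: {sorted(shapes)}")
        arr = np.stack(slices)       # (n_slices, height, width)
    data = (arr > 0).transpose(2, 1, 0)   # → (width, height, n_slices)
    spec = GridSpec(tuple(origin), voxel_size, data.shape)
    return BitVolumeGrid(spec, data)
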
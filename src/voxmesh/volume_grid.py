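"""Uniform 3D Cartesian occupancy and annotation grids anchored in world space.

A grid is defined by a :class:`GridSpec`: a world-space origin (μm), an
isotropic voxel side length (μm) and integer dimensions.  Voxel ``i``
(0-based) spans the half-open world interval ``[origin + i*h, origin +
(i+1)*h)`` so every world point belongs to exactly one voxel.

Occupancy grids store one bit per voxel when serialized (``ceil(N/8)``
bytes for ``N`` voxels); in memory a boolean numpy array is used for
vectorized access.  Annotated grids store one non-negative integer label
per voxel, 0 meaning background.

Supported on-disk forms: a RAW payload with an ASCII ``.hdr`` companion
(1-bit packed or uint8/16/32/64), and NRRD with an inline text header.
Payload axis order is x fastest, then y, then z; the headers state this.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "BitVolumeGrid",
    "AnnotatedVoxelGrid",
    "GridCompatibilityError",
    "VolumeFormatError",
    "grid_from_aabb",
    "voxel_world_box",
    "count_set",
    "tag_occupancy",
    "write_volume",
    "read_volume",
]


class VolumeFormatError(ValueError):
    """Malformed volume file: bad header field or payload size mismatch."""


class GridCompatibilityError(ValueError):
    """Operation combining grids whose GridSpecs differ."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a uniform isotropic voxel grid.

    Parameters
    ----------
    origin : (3,) float
        World-space position (μm) of the minimum corner of voxel (0,0,0).
    voxel_size : float
        Side length of every voxel (μm); must be positive.
    dims : (3,) int
        Number of voxels along x, y, z; each at least 1.
    """

    origin: tuple[float, float, float]
    voxel_size: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", float(self.voxel_size))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def aabb(self) -> np.ndarray:
        """World AABB ``[min, max]`` of the grid, shape (2, 3)."""
        o = np.asarray(self.origin, dtype=float)
        return np.stack([o, o + np.asarray(self.dims) * self.voxel_size])

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points to integer voxel indices (floor convention)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((p - np.asarray(self.origin)) / self.voxel_size).astype(np.int64)

    def index_to_center(self, indices: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + (i + 0.5) * self.voxel_size


@dataclass
class BitVolumeGrid:
    """Occupancy grid; ``data`` is a bool array of shape ``dims`` (x, y, z)."""

    spec: GridSpec
    data: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.data is None:
            self.data = np.zeros(self.spec.dims, dtype=bool)
        else:
            self.data = np.ascontiguousarray(self.data, dtype=bool)
            if self.data.shape != tuple(self.spec.dims):
                raise GridCompatibilityError(
                    f"data shape {self.data.shape} != dims {self.spec.dims}")

    def copy(self) -> "BitVolumeGrid":
        return BitVolumeGrid(self.spec, self.data.copy())


@dataclass
class AnnotatedVoxelGrid:
    """Label grid; ``labels`` is a non-negative integer array of shape ``dims``."""

    spec: GridSpec
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.labels is None:
            self.labels = np.zeros(self.spec.dims, dtype=np.uint32)
        else:
            self.labels = np.ascontiguousarray(self.labels)
            if self.labels.shape != tuple(self.spec.dims):
                raise GridCompatibilityError(
                    f"labels shape {self.labels.shape} != dims {self.spec.dims}")
            if np.issubdtype(self.labels.dtype, np.signedinteger) and self.labels.min(initial=0) < 0:
                raise ValueError("labels must be non-negative")


def grid_from_aabb(aabb, resolution: float, padding_voxels: int = 2) -> GridSpec:
    """Build a GridSpec covering a world AABB at ``resolution`` voxels/μm.

    The grid covers the AABB expanded by ``padding_voxels`` voxels on every
    side; per axis ``dims = ceil(extent * resolution) + 2 * padding_voxels``.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0 voxels/micron, got {resolution}")
    if padding_voxels < 0:
        raise ValueError("padding_voxels must be >= 0")
    box = np.asarray(aabb, dtype=float).reshape(2, 3)
    extent = box[1] - box[0]
    if np.any(extent <= 0):
        raise ValueError(f"aabb degenerate on some axis: extent {extent}")
    h = 1.0 / float(resolution)
    core = np.ceil(extent * resolution - 1e-9).astype(int)  # guard exact multiples
    core = np.maximum(core, 1)
    dims = core + 2 * padding_voxels
    # center the (slightly larger) covered extent on the input box
    slack = core * h - extent
    origin = box[0] - slack / 2.0 - padding_voxels * h
    return GridSpec(tuple(origin), h, tuple(int(d) for d in dims))


def voxel_world_box(spec: GridSpec, index) -> np.ndarray:
    """World AABB ``[min, max]`` of one voxel, shape (2, 3)."""
    idx = np.asarray(index, dtype=np.int64)
    if idx.shape != (3,):
        raise IndexError(f"index must be a 3-tuple, got {index}")
    if np.any(idx < 0) or np.any(idx >= np.asarray(spec.dims)):
        raise IndexError(f"index {tuple(idx)} out of range for dims {spec.dims}")
    lo = np.asarray(spec.origin) + idx * spec.voxel_size
    return np.stack([lo, lo + spec.voxel_size])


def count_set(grid: BitVolumeGrid) -> int:
    """Number of set voxels."""
    return int(np.count_nonzero(grid.data))


def tag_occupancy(target: AnnotatedVoxelGrid, source: BitVolumeGrid,
                  label: int) -> AnnotatedVoxelGrid:
    """Paint ``label`` into ``target`` wherever ``source`` is set (in place).

    Later calls overwrite earlier labels on overlapping voxels.
    """
    if target.spec != source.spec:
        raise GridCompatibilityError(
            f"grid specs differ: {target.spec} vs {source.spec}")
    if label < 0:
        raise ValueError("label must be non-negative")
    target.labels[source.data] = label
    return target


# ---------------------------------------------------------------------------
# serialization

_DTYPES = {"uint8": np.uint8, "uint16": np.uint16,
           "uint32": np.uint32, "uint64": np.uint64}


def _write_hdr(path: str, spec: GridSpec, typename: str) -> None:
    nx, ny, nz = spec.dims
    ox, oy, oz = spec.origin
    with open(path, "w") as fh:
        fh.write(f"dims {nx} {ny} {nz}\n")
        fh.write(f"type {typename}\n")
        fh.write(f"voxel_size {spec.voxel_size!r}\n")
        fh.write(f"origin {ox!r} {oy!r} {oz!r}\n")
        fh.write("axis_order x-fastest\n")


def _read_hdr(path: str) -> tuple[GridSpec, str]:
    fields: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                fields[parts[0]] = parts[1:]
    try:
        dims = tuple(int(v) for v in fields["dims"])
        typename = fields["type"][0]
        h = float(fields["voxel_size"][0])
        origin = tuple(float(v) for v in fields["origin"])
    except (KeyError, IndexError, ValueError) as exc:
        raise VolumeFormatError(f"malformed header {path}: {exc!r}") from exc
    if len(dims) != 3 or len(origin) != 3:
        raise VolumeFormatError(f"header {path}: dims/origin must have 3 values")
    if typename not in ("bit", *_DTYPES):
        raise VolumeFormatError(f"header {path}: unknown type {typename!r}")
    return GridSpec(origin, h, dims), typename


def _pack_bits(data: np.ndarray) -> bytes:
    # x fastest: transpose to (z, y, x) C-order then ravel; LSB-first packing
    flat = np.ascontiguousarray(data.transpose(2, 1, 0)).ravel()
    return np.packbits(flat.astype(np.uint8), bitorder="little").tobytes()


def _unpack_bits(raw: bytes, dims) -> np.ndarray:
    n = int(np.prod(dims))
    flat = np.unpackbits(np.frombuffer(raw, dtype=np.uint8),
                         count=n, bitorder="little").astype(bool)
    return flat.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)


def write_volume(grid, path: str, format: str = "bit+hdr") -> None:
    """Write a grid to disk.

    ``format``: ``bit+hdr`` (1-bit packed payload, occupancy grids only),
    ``raw8+hdr`` (uint8 payload; labels need ``raw8``/NRRD), or ``nrrd``.
    The RAW/BIT payload goes to ``path`` and the header to ``path + '.hdr'``.
    """
    is_bits = isinstance(grid, BitVolumeGrid)
    if format == "bit+hdr":
        if not is_bits:
            raise VolumeFormatError("bit+hdr stores occupancy grids only")
        with open(path, "wb") as fh:
            fh.write(_pack_bits(grid.data))
        _write_hdr(path + ".hdr", grid.spec, "bit")
    elif format == "raw8+hdr":
        arr = grid.data.astype(np.uint8) if is_bits else grid.labels
        if arr.dtype not in (np.uint8,):
            arr = _fit_dtype(arr)
        name = arr.dtype.name
        if name not in _DTYPES:
            raise VolumeFormatError(f"unsupported dtype {name}")
        with open(path, "wb") as fh:
            fh.write(np.ascontiguousarray(arr.transpose(2, 1, 0)).tobytes())
        _write_hdr(path + ".hdr", grid.spec, name)
    elif format == "nrrd":
        arr = grid.data.astype(np.uint8) if is_bits else _fit_dtype(grid.labels)
        _write_nrrd(path, grid.spec, arr, occupancy=is_bits)
    else:
        raise VolumeFormatError(f"unknown volume format {format!r}")


def _fit_dtype(labels: np.ndarray) -> np.ndarray:
    hi = int(labels.max(initial=0))
    for name in ("uint8", "uint16", "uint32", "uint64"):
        if hi <= np.iinfo(_DTYPES[name]).max:
            return labels.astype(_DTYPES[name])
    raise VolumeFormatError("label values exceed uint64")


def read_volume(path: str):
    """Read a grid written by :func:`write_volume` (auto-detects NRRD)."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic.startswith(b"NRRD"):
        return _read_nrrd(path)
    spec, typename = _read_hdr(path + ".hdr")
    with open(path, "rb") as fh:
        raw = fh.read()
    n = spec.n_voxels
    if typename == "bit":
        expect = (n + 7) // 8
        if len(raw) != expect:
            raise VolumeFormatError(
                f"{path}: payload size {len(raw)} != ceil(dims product/8) = {expect}")
        return BitVolumeGrid(spec, _unpack_bits(raw, spec.dims))
    dt = np.dtype(_DTYPES[typename])
    if len(raw) != n * dt.itemsize:
        raise VolumeFormatError(
            f"{path}: payload size {len(raw)} != dims product * itemsize = {n * dt.itemsize}")
    arr = np.frombuffer(raw, dtype=dt).reshape(
        spec.dims[2], spec.dims[1], spec.dims[0]).transpose(2, 1, 0)
    if typename == "uint8" and arr.max(initial=0) <= 1:
        return BitVolumeGrid(spec, arr.astype(bool))
    return AnnotatedVoxelGrid(spec, arr.copy())


# minimal NRRD-0004: inline ASCII header, raw little-endian payload
def _write_nrrd(path: str, spec: GridSpec, arr: np.ndarray, occupancy: bool) -> None:
    header = [
        "NRRD0004",
        "# voxmesh volume (axis order: x fastest)",
        f"type: {arr.dtype.name}",
        "dimension: 3",
        f"sizes: {spec.dims[0]} {spec.dims[1]} {spec.dims[2]}",
        "encoding: raw",
        "endian: little",
        "space dimension: 3",
        f"space origin: ({spec.origin[0]!r},{spec.origin[1]!r},{spec.origin[2]!r})",
        ("space directions: "
         f"({spec.voxel_size!r},0,0) (0,{spec.voxel_size!r},0) (0,0,{spec.voxel_size!r})"),
        f"# occupancy: {int(occupancy)}",
        "",
        "",
    ]
    payload = np.ascontiguousarray(
        arr.astype(arr.dtype.newbyteorder("<")).transpose(2, 1, 0)).tobytes()
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(payload)


def _read_nrrd(path: str):
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        head, payload = raw.split(b"\n\n", 1)
    except ValueError as exc:
        raise VolumeFormatError(f"{path}: missing NRRD header terminator") from exc
    fields: dict[str, str] = {}
    occupancy = False
    for line in head.decode("ascii").splitlines()[1:]:
        if line.startswith("# occupancy:"):
            occupancy = line.split(":")[1].strip() == "1"
        elif ":" in line and not line.startswith("#"):
            key, val = line.split(":", 1)
            fields[key.strip()] = val.strip()
    try:
        dims = tuple(int(v) for v in fields["sizes"].split())
        dtype = np.dtype(fields["type"])
        origin = tuple(float(v) for v in
                       fields["space origin"].strip("()").split(","))
        h = float(fields["space directions"].split(")")[0].strip("(").split(",")[0])
    except (KeyError, ValueError) as exc:
        raise VolumeFormatError(f"{path}: malformed NRRD header field: {exc!r}") from exc
    spec = GridSpec(origin, h, dims)
    n = spec.n_voxels
    if len(payload) != n * dtype.itemsize:
        raise VolumeFormatError(
            f"{path}: payload size {len(payload)} != sizes product * itemsize")
    arr = np.frombuffer(payload, dtype=dtype).reshape(
        dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    if occupancy:
        return BitVolumeGrid(spec, arr.astype(bool))
    return AnnotatedVoxelGrid(spec, arr.copy())
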
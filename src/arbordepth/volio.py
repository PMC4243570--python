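"""Core containers, file I/O, configuration and logging.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)``; ``z`` is the laminar axis and increases
  from the ganglion-cell side of the tissue toward the inner nuclear layer.
* Physical coordinates are in micrometers.  The physical position of voxel
  index ``(i, j, k)`` is ``origin + (i*dx, j*dy, k*dz)``.
* On-disk image stacks are grayscale multi-page TIFFs; page index maps to
  the ``z`` index.  Skeleton traces use the 7-column SWC dialect.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

log = logging.getLogger("arbordepth")

__all__ = [
    "VoxelGrid",
    "ImageStack",
    "BinaryVolume",
    "SkeletonNode",
    "Skeleton",
    "FormatError",
    "read_stack",
    "write_stack",
    "read_swc",
    "write_swc",
    "rasterize_skeleton",
    "load_config",
    "setup_logging",
    "stage_timer",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform 3-D sampling lattice: shape (nx, ny, nz), pitch in μm."""

    shape: tuple[int, int, int]
    pitch: tuple[float, float, float] = (0.4, 0.4, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.pitch) != 3 or any(p <= 0 for p in self.pitch):
            raise ValueError(f"pitch must be three positive numbers, got {self.pitch}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "pitch", tuple(float(p) for p in self.pitch))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical μm coordinates of (..., 3) voxel indices."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.pitch)

    def to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index of (..., 3) physical coordinates.

        Ties (exact half-pitch positions) round toward the smaller index.
        """
        xyz = np.asarray(xyz, dtype=float)
        frac = (xyz - np.asarray(self.origin)) / np.asarray(self.pitch)
        return np.ceil(frac - 0.5).astype(np.int64)


@dataclass
class ImageStack:
    """Single-channel scalar intensity volume with a channel-role tag."""

    grid: VoxelGrid
    values: np.ndarray
    role: str = "neuron"  # "neuron" | "fiducial"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stack values must be finite")
        if self.role not in ("neuron", "fiducial"):
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class BinaryVolume:
    """Boolean mask on a voxel grid."""

    grid: VoxelGrid
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if tuple(self.mask.shape) != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SkeletonNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for roots


@dataclass
class Skeleton:
    """SWC-style tree: nodes with parent pointers (parent -1 = root)."""

    nodes: list[SkeletonNode] = field(default_factory=list)

    def __post_init__(self):
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate node ids in skeleton")
        idset = set(ids)
        for n in self.nodes:
            if n.parent != -1 and n.parent not in idset:
                raise FormatError(f"node {n.id} has dangling parent {n.parent}")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def roots(self) -> list[SkeletonNode]:
        return [n for n in self.nodes if n.parent == -1]

    def edges(self) -> list[tuple[SkeletonNode, SkeletonNode]]:
        """(parent, child) pairs."""
        by_id = {n.id: n for n in self.nodes}
        return [(by_id[n.parent], n) for n in self.nodes if n.parent != -1]

    def coords(self) -> np.ndarray:
        return np.array([(n.x, n.y, n.z) for n in self.nodes], dtype=float)


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(path, pitch, role: str = "neuron", origin=(0.0, 0.0, 0.0)) -> ImageStack:
    """Read a grayscale multi-page TIFF as an ImageStack.

    Pages map to z; pixel values are preserved losslessly (no rescaling).
    """
    if any(p <= 0 for p in pitch):
        raise FormatError(f"nonpositive pitch {pitch}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            arr = series.asarray()
    except FormatError:
        raise
    except Exception as e:  # noqa: BLE001 - normalize to format error
        raise FormatError(f"cannot read TIFF {path}: {e}") from e
    if "S" in axes or "C" in axes:
        raise FormatError(f"{path}: multi-sample pages (axes {axes}) are not grayscale")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected single-sample grayscale pages, got shape {arr.shape}"
        )
    # tifffile yields (z, y, x); package convention is (x, y, z)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    grid = VoxelGrid(values.shape, tuple(pitch), tuple(origin))
    return ImageStack(grid, values, role)


def write_stack(path, stack: ImageStack) -> None:
    """Write an ImageStack (or BinaryVolume via 0/255) as a multi-page TIFF."""
    if isinstance(stack, BinaryVolume):
        values = stack.mask.astype(np.uint8) * 255
    else:
        values = stack.values
    tifffile.imwrite(
        path,
        np.ascontiguousarray(values.transpose(2, 1, 0)),
        photometric="minisblack",
    )


# ---------------------------------------------------------------------------
# SWC skeletons


def read_swc(path) -> Skeleton:
    """Parse a 7-column SWC file. Coordinates are kept in the file's μm units."""
    nodes: list[SkeletonNode] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, tc = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: unparsable field ({e})") from e
            if nid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate node id {nid}")
            seen.add(nid)
            nodes.append(SkeletonNode(nid, tc, x, y, z, r, parent))
    for i, n in enumerate(nodes, start=1):
        if n.parent != -1 and n.parent not in seen:
            # recover original line number for the error message
            raise FormatError(
                f"{path}: node id {n.id} (entry {i}) references missing parent {n.parent}"
            )
    return Skeleton(nodes)


def write_swc(path, s: Skeleton) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in s.nodes:
            fh.write(f"{n.id} {n.type_code} {n.x:.4f} {n.y:.4f} {n.z:.4f} {n.radius:.4f} {n.parent}\n")


# ---------------------------------------------------------------------------
# Rasterization


def _digital_line(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """26-connected single-voxel-wide digital line between integer voxels a, b.

    Steps along the dominant axis; the other coordinates are rounded with
    ties toward the smaller index (deterministic Bresenham-style stepping).
    Includes both endpoints.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    d = b - a
    n = int(np.max(np.abs(d)))
    if n == 0:
        return a[None, :]
    t = np.arange(n + 1, dtype=float) / n
    pts = a[None, :] + t[:, None] * d[None, :]
    return np.ceil(pts - 0.5).astype(np.int64)


def rasterize_skeleton(s: Skeleton, grid: VoxelGrid) -> BinaryVolume:
    """Draw the skeleton as 26-connected digital lines of unit width.

    Node radii are ignored: dendrite thickness is supplied later by
    topologically constrained inflation, not by the trace.

    Edges are drawn in breadth-first order and each edge's line is
    truncated at its first contact (walking from the child end) with the
    voxels already drawn.  Every edge therefore attaches as a simple arc,
    which keeps the rendering homotopy-equivalent to the tree: naive
    overdrawing of lines that share a node can otherwise enclose spurious
    one-voxel tunnels where the two digital staircases braid.
    """
    if len(s) == 0:
        raise ValueError("empty skeleton")
    idx = grid.to_index(s.coords())
    shape = np.asarray(grid.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        bad = s.nodes[int(np.argmax(np.any((idx < 0) | (idx >= shape), axis=1)))]
        raise ValueError(f"skeleton node {bad.id} falls outside the grid")

    padded = np.zeros(tuple(shape + 2), dtype=bool)  # pad for adjacency tests
    by_id = {n.id: i for i, n in enumerate(s.nodes)}
    children: dict[int, list[int]] = {}
    order: list[int] = []
    for i, n in enumerate(s.nodes):
        if n.parent == -1:
            padded[tuple(idx[i] + 1)] = True
            order.append(i)
        else:
            children.setdefault(by_id[n.parent], []).append(i)
    qi = 0
    while qi < len(order):
        for child in children.get(order[qi], []):
            order.append(child)
            line = _digital_line(idx[order[qi]], idx[child]) + 1
            # first contact with the drawn set, walking child -> parent
            start = 0
            for k in range(len(line) - 1, -1, -1):
                x, y, z = line[k]
                if padded[x - 1:x + 2, y - 1:y + 2, z - 1:z + 2].any():
                    start = k
                    break
            seg = line[start:]
            padded[seg[:, 0], seg[:, 1], seg[:, 2]] = True
        qi += 1
    if len(order) < len(s.nodes):
        raise ValueError("skeleton is not a forest reachable from its roots")
    return BinaryVolume(grid, padded[1:-1, 1:-1, 1:-1])


# ---------------------------------------------------------------------------
# Config and logging


def load_config(path, known_keys=None) -> dict:
    """Load a flat key/value YAML config; reject unknown or nested keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a flat mapping")
    for k, v in cfg.items():
        if isinstance(v, (dict,)):
            raise FormatError(f"{path}: nested config key {k!r} not allowed")
    if known_keys is not None:
        unknown = set(cfg) - set(known_keys)
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


@contextmanager
def stage_timer(name: str):
    """Log wall-clock duration of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    try:
        yield
    finally:
        log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
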
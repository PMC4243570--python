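"""3-D digital topology: simple points and topologically constrained inflation.

The adjacency pair is fixed at (26, 6): foreground components are
26-connected, background components are 6-connected.  A voxel is *simple*
when flipping it leaves the topology of the digital image unchanged
(no object, tunnel or cavity is created or destroyed).  Simplicity is
decided locally on the 3x3x3 neighborhood through the two topological
numbers of Bertrand & Malandain: the number of 26-components of the
foreground in the 26-neighborhood, and the number of 6-components of the
background in the 18-neighborhood that touch a face neighbor.  The voxel
is simple iff both numbers equal 1.

Inflation grows a skeleton trace outward into bright image voxels, one
voxel layer per round, flipping only simple points, so the result is
homotopy-equivalent to the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import euler_number

from .volio import BinaryVolume, ImageStack

__all__ = [
    "TopologySummary",
    "is_simple_point",
    "simple_point_code",
    "pack_neighborhood",
    "topology_summary",
    "inflate_trace",
    "max_absorbable_diameter",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

# --- static neighborhood geometry -----------------------------------------
# Offsets of the 26 neighbors in raveled 3x3x3 order (center excluded).
_OFFSETS = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int8,
)
_N26 = len(_OFFSETS)  # 26

# indices (into _OFFSETS) of the 18-neighborhood and the 6 face neighbors
_IDX18 = [i for i, o in enumerate(_OFFSETS) if int(np.sum(np.abs(o))) <= 2]
_IDX6 = [i for i, o in enumerate(_OFFSETS) if int(np.sum(np.abs(o))) == 1]


def _adjacency(indices, metric):
    """Adjacency lists between offset positions under the given test."""
    adj = {i: [] for i in indices}
    for i in indices:
        for j in indices:
            if i != j and metric(_OFFSETS[i], _OFFSETS[j]):
                adj[i].append(j)
    return adj

_ADJ26 = _adjacency(range(_N26), lambda a, b: np.max(np.abs(a - b)) <= 1)
_ADJ6_18 = _adjacency(_IDX18, lambda a, b: np.sum(np.abs(a - b)) == 1)

# bit weight of each neighbor in the packed 26-bit code
_BITS = (1 << np.arange(_N26, dtype=np.int64))

_simple_cache: dict[int, bool] = {}


def pack_neighborhood(patch: np.ndarray) -> int:
    """Pack the 26 neighbor values of a 3x3x3 boolean patch into an int code.

    The center value is irrelevant to simplicity and is not encoded.
    """
    flat = np.asarray(patch, dtype=bool).ravel()
    if flat.size != 27:
        raise ValueError("neighborhood patch must be 3x3x3")
    neigh = np.delete(flat, 13)
    return int(np.dot(neigh, _BITS))


def _count_components(members: list[int], adj) -> int:
    seen: set[int] = set()
    comps = 0
    mset = set(members)
    for start in members:
        if start in seen:
            continue
        comps += 1
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w in mset and w not in seen:
                    seen.add(w)
                    stack.append(w)
    return comps


def simple_point_code(code: int) -> bool:
    """Simplicity decision for a packed 26-bit neighborhood code (memoized)."""
    hit = _simple_cache.get(code)
    if hit is not None:
        return hit
    fg = [i for i in range(_N26) if (code >> i) & 1]
    # T26: 26-components of foreground among the 26 neighbors
    t26 = _count_components(fg, _ADJ26)
    if t26 != 1:
        _simple_cache[code] = False
        return False
    # T6: 6-components of background within the 18-neighborhood that
    # contain at least one face neighbor of the center
    bg18 = [i for i in _IDX18 if not (code >> i) & 1]
    bgset = set(bg18)
    seen: set[int] = set()
    t6 = 0
    for start in _IDX6:
        if start not in bgset or start in seen:
            continue
        t6 += 1
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            for w in _ADJ6_18[v]:
                if w in bgset and w not in seen:
                    seen.add(w)
                    stack.append(w)
    result = t6 == 1
    _simple_cache[code] = result
    return result


def is_simple_point(patch: np.ndarray) -> bool:
    """True iff flipping the center of the 3x3x3 patch preserves topology.

    Decided under the (26-foreground, 6-background) adjacency pair; the
    answer does not depend on the current center value (flip symmetry).
    """
    return simple_point_code(pack_neighborhood(patch))


# ---------------------------------------------------------------------------
# Global topology summary (independent oracle for topology preservation)


@dataclass(frozen=True)
class TopologySummary:
    components: int  # 26-connected foreground components
    cavities: int    # fully enclosed 6-connected background components
    euler: int       # Euler characteristic under 26-connectivity

    def as_tuple(self):
        return (self.components, self.cavities, self.euler)


def topology_summary(v) -> TopologySummary:
    """Component / cavity / Euler counts of a boolean volume.

    Counts are computed on the volume padded by one background layer, so
    foreground touching the border is handled consistently.
    """
    mask = v.mask if isinstance(v, BinaryVolume) else np.asarray(v, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    _, ncomp = ndimage.label(padded, structure=_STRUCT26)
    _, nbg = ndimage.label(~padded, structure=_STRUCT6)
    cavities = nbg - 1  # the pad layer connects all exterior background
    euler = int(euler_number(padded, connectivity=3)) if ncomp else 0
    return TopologySummary(int(ncomp), int(cavities), euler)


# ---------------------------------------------------------------------------
# Algorithm: topologically constrained inflation of a trace


def _candidate_order(cand: np.ndarray) -> np.ndarray:
    """Sort candidate voxel indices in raster order, x fastest."""
    return cand[np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))]


def inflate_trace(
    raw: ImageStack,
    trace: BinaryVolume,
    max_radius: int = 62,
    threshold_frac: float = 0.6,
    live: bool = True,
) -> BinaryVolume:
    """Inflate a rasterized trace into bright voxels without changing topology.

    ``target`` is the set of voxels at or above ``threshold_frac`` times the
    global intensity maximum.  Each of ``max_radius`` rounds considers the
    6-neighborhood dilation shell of the current volume; shell voxels in the
    target are flipped on one at a time, only when simple.  Sweeps repeat
    until the number of remaining difference voxels stabilizes.

    With ``live=True`` (default) every simplicity test reads the up-to-date
    volume, which provably preserves topology under sequential flips.
    ``live=False`` reproduces a literal per-round stale-copy reading of the
    pseudocode for comparison (its guarantee is weaker).

    Returns a volume that is a superset of the trace, a subset of
    trace ∪ target, and (for ``live=True``) has the same TopologySummary
    as the trace.
    """
    if raw.grid.shape != trace.grid.shape:
        raise ValueError("raw stack and trace must share a grid")
    if not trace.mask.any():
        raise ValueError("trace is empty")
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must be in (0, 1]")

    target = raw.values >= threshold_frac * raw.values.max()
    # pad by one background voxel so 3x3x3 patches are always in-bounds
    vol = np.pad(trace.mask, 1, constant_values=False).astype(np.uint8)
    tgt = np.pad(target, 1, constant_values=False)
    sweep_cap = 10 * max(vol.shape)

    for _ in range(int(max_radius)):
        shell = ndimage.binary_dilation(vol.astype(bool), structure=_STRUCT6) & (vol == 0)
        if not (shell & tgt).any():
            break  # idempotent once shell ∩ target is empty
        prev_diff, cur_diff = -1, 0
        sweeps = 0
        while cur_diff != prev_diff and sweeps < sweep_cap:
            snapshot = vol.copy()
            patches_src = vol if live else snapshot
            diff = shell & tgt & (vol == 0)
            cand = _candidate_order(np.argwhere(diff))
            for x, y, z in cand:
                patch = patches_src[x - 1:x + 2, y - 1:y + 2, z - 1:z + 2]
                if simple_point_code(int(np.dot(patch.ravel(), _PATCH_BITS))):
                    vol[x, y, z] = 1
            prev_diff = cur_diff
            cur_diff = int((shell & tgt & (vol == 0)).sum())
            sweeps += 1
    return BinaryVolume(trace.grid, vol[1:-1, 1:-1, 1:-1].astype(bool))


# bit weights aligned with raveled 3x3x3 patches (center weight zero)
_PATCH_BITS = np.insert(_BITS.astype(np.int64), 13, 0)


def max_absorbable_diameter(max_radius: int, pitch: float) -> float:
    """Diameter (μm) of the largest sphere fully absorbed by inflation.

    Each round can add a single voxel layer around the current volume, so
    starting from one seed voxel, ``max_radius`` rounds cover a diameter of
    ``(2 * max_radius + 1)`` voxels.
    """
    if max_radius < 0 or pitch <= 0:
        raise ValueError("max_radius must be >= 0 and pitch > 0")
    return (2 * int(max_radius) + 1) * float(pitch)
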
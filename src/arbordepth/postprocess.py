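"""Post-processing of an enhanced volume: isolate the neuron of interest.

Stages, in order: min-max normalization; binarize at 0.7 and dilate to
bridge small gaps; keep the intensity under the largest 26-connected
dilated component; re-binarize conservatively at 0.5; drop small objects;
and remove soma-like lumps — any region thick enough to fully enclose a
digital ball of the search radius, plus a one-radius guard margin, is
deleted (opening followed by dilation with the same ball).

Ball erosions/dilations are computed through Euclidean distance
transforms, which is exact for digital-ball structuring elements and much
faster than explicit kernels at the radii used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import BinaryVolume, ImageStack

__all__ = [
    "PostprocessParams",
    "postprocess",
    "remove_small_objects",
    "ball_dilate",
    "ball_erode",
    "ball_open",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PostprocessParams:
    dilation_radius: int = 2     # voxels; bridges breaks before labeling
    size_threshold: int = 500    # voxels; minimum surviving object volume
    search_radius: int = 10      # voxels; lump (soma) ball radius
    threshold: float = 0.7
    conservative_threshold: float = 0.5
    kernel: str = "ball"         # "ball" | "cube"

    def __post_init__(self):
        if self.dilation_radius < 1 or self.search_radius < 1 or self.size_threshold < 1:
            raise ValueError("radii and size threshold must be >= 1")
        if not (0 < self.conservative_threshold <= self.threshold <= 1):
            raise ValueError("need 0 < conservative_threshold <= threshold <= 1")
        if self.kernel not in ("ball", "cube"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def _ball_struct(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return X ** 2 + Y ** 2 + Z ** 2 <= radius * radius


def _dilate(mask: np.ndarray, radius: int, kernel: str) -> np.ndarray:
    if kernel == "cube":
        size = 2 * radius + 1
        return ndimage.maximum_filter(mask.astype(np.uint8), size=size).astype(bool)
    if radius <= 3:  # explicit small kernel beats a full distance transform
        return ndimage.binary_dilation(mask, structure=_ball_struct(radius))
    return ball_dilate(mask, radius)


def _erode(mask: np.ndarray, radius: int, kernel: str) -> np.ndarray:
    if kernel == "cube":
        size = 2 * radius + 1
        return ndimage.minimum_filter(mask.astype(np.uint8), size=size).astype(bool)
    return ball_erode(mask, radius)


def ball_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation by the digital ball {v : |v| <= radius} via the EDT."""
    if not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask)
    return d <= radius


def ball_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion by the digital ball; the outside of the volume is background."""
    if not mask.any():
        return mask.copy()
    padded = np.pad(mask, radius, constant_values=False)
    d = ndimage.distance_transform_edt(padded)
    out = d > radius
    sl = tuple(slice(radius, -radius) for _ in range(mask.ndim))
    return out[sl]


def ball_open(mask: np.ndarray, radius: int) -> np.ndarray:
    return ball_dilate(ball_erode(mask, radius), radius)


def remove_small_objects(v: BinaryVolume, min_voxels: int) -> BinaryVolume:
    """Drop 26-connected components with fewer than ``min_voxels`` voxels."""
    if min_voxels <= 1 or not v.mask.any():
        return BinaryVolume(v.grid, v.mask.copy())
    labels, n = ndimage.label(v.mask, structure=_STRUCT26)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return BinaryVolume(v.grid, keep[labels])


def postprocess(prob: ImageStack, p: PostprocessParams | None = None) -> BinaryVolume:
    """Run the full cleanup chain on an enhanced (or thresholded) stack."""
    p = p or PostprocessParams()
    values = np.asarray(prob.values, dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        raise ValueError("constant stack: normalization undefined")
    norm = (values - vmin) / (vmax - vmin)

    # bridge nearby pieces, then keep everything under the largest component
    connected = _dilate(norm > p.threshold, p.dilation_radius, p.kernel)
    labels, n = ndimage.label(connected, structure=_STRUCT26)
    if n == 0:
        raise ValueError("nothing above threshold after normalization")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    # tie-break: among equally large components, keep the one whose smallest
    # linear voxel index is smallest (first encountered in raster order)
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) == 1:
        largest = candidates[0]
    else:
        flat = labels.ravel()
        firsts = {c: np.argmax(flat == c) for c in candidates}
        largest = min(candidates, key=lambda c: firsts[c])
    retained = np.where(labels == largest, norm, 0.0)

    mask = retained > p.conservative_threshold
    mask = remove_small_objects(BinaryVolume(prob.grid, mask), p.size_threshold).mask

    # soma/lump removal: regions enclosing a search-radius ball, plus margin.
    # Computed on the mask bounding box (grown by 3 radii, so no lump can
    # reach the crop border) — identical result, much less volume.
    out = mask.copy()
    if mask.any():
        r = p.search_radius
        obj = ndimage.find_objects(mask.astype(np.uint8), max_label=1)[0]
        sl = tuple(
            slice(max(0, s.start - 3 * r - 1), min(n, s.stop + 3 * r + 1))
            for s, n in zip(obj, mask.shape)
        )
        sub = mask[sl]
        lumps = _dilate(_dilate(_erode(sub, r, p.kernel), r, p.kernel), r, p.kernel)
        out[sl] = sub & ~lumps
    return BinaryVolume(prob.grid, out)
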
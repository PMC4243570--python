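"""Synthetic confocal phantoms: stratified arbors, wavy laminae, noise.

A phantom emulates a two-channel confocal stack of one sparsely labeled
retinal ganglion cell: a branching dendritic arbor confined to its
type-specific laminar depth(s) with submicron jitter, a soma below the On
lamina connected by a primary dendrite, and a fiducial channel holding the
two starburst laminae as bright wavy sheets 12 μm apart.  Both channels
are blurred by a Gaussian PSF and corrupted by Poisson shot noise plus
Gaussian read noise.  The generator records exact ground truth (skeleton,
tube mask, lamina heights, per-voxel arbor depth), so every pipeline stage
can be scored without external data.

Type target depths (μm from the On starburst surface): JAMB 15.6, W3 5.5,
BDa 0.3 and 12.3 (bistratified, the second stratum 0.3 μm beyond the Off
surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .laminar import OFF_DEPTH_UM, Surface
from .volio import BinaryVolume, ImageStack, Skeleton, SkeletonNode, VoxelGrid

__all__ = [
    "TYPE_DEPTHS_UM",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "add_distractors",
]

TYPE_DEPTHS_UM = {
    "JAMB": (15.6,),
    "W3": (5.5,),
    "BDa": (0.3, 12.3),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic stack."""

    shape: tuple[int, int, int] = (256, 256, 120)
    pitch: tuple[float, float, float] = (0.4, 0.4, 0.5)
    cell_type: str = "W3"
    jitter_um: float = 0.25            # across-cell laminar jitter (SD)
    warp_amplitude_um: float = 4.0     # sinusoidal lamina waviness
    warp_wavelength_um: float = 100.0
    radius_root_um: float = 1.5        # dendrite taper, root -> tip
    radius_tip_um: float = 0.3
    soma_diameter_um: float = 12.0
    soma_depth_um: float = -8.0        # soma center, μm from the On surface
    on_base_um: float = 20.0           # mean z of the On lamina
    blur_sigma_um: tuple[float, float, float] = (0.3, 0.3, 0.6)
    read_noise_frac: float = 0.02      # Gaussian read noise, fraction of peak
    peak_photons: float = 400.0
    branch_prob: float = 0.05          # per 1 μm growth step
    step_um: float = 1.0
    persistence: float = 0.8           # in-plane direction memory
    stratum_length_um: float = 1200.0  # total dendrite length per stratum
    seed: int = 0

    def __post_init__(self):
        if self.cell_type not in TYPE_DEPTHS_UM:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        nz_um = (self.shape[2] - 1) * self.pitch[2]
        amp = self.warp_amplitude_um
        lo = self.on_base_um - amp
        hi = self.on_base_um + amp + OFF_DEPTH_UM
        if lo < 5.0 or hi > nz_um - 5.0:
            raise ValueError("lamina waviness leaves less than 5 μm border margin")
        for d in TYPE_DEPTHS_UM[self.cell_type]:
            if not (lo - 15.0 < d + self.on_base_um < nz_um - 2.0):
                raise ValueError(f"target depth {d} μm incompatible with the grid")


@dataclass
class PhantomTruth:
    """Exact ground truth recorded while rendering a phantom."""

    skeleton: Skeleton
    true_volume: BinaryVolume          # soma + trunk + arbor tubes, pre-blur
    surfaces: tuple[Surface, Surface]  # true (On, Off) height maps
    arbor_depths_um: np.ndarray        # true depth of every arbor tube voxel
    arbor_mask: np.ndarray             # arbor tubes only (no soma/trunk)
    stratum_offsets_um: tuple = ()     # realized laminar jitter per stratum


def _ball_offsets(radius_um: float, pitch) -> np.ndarray:
    """Integer voxel offsets covered by a ball of the given physical radius."""
    ext = [max(0, int(np.floor(radius_um / p))) for p in pitch]
    ox, oy, oz = np.meshgrid(*(np.arange(-e, e + 1) for e in ext), indexing="ij")
    d2 = (ox * pitch[0]) ** 2 + (oy * pitch[1]) ** 2 + (oz * pitch[2]) ** 2
    keep = d2 <= radius_um ** 2 + 1e-12
    return np.column_stack([ox[keep], oy[keep], oz[keep]])


class _Stamper:
    """Stamps balls of quantized radii into a boolean volume."""

    def __init__(self, shape, pitch, quantum_um: float = 0.1):
        self.shape = np.asarray(shape)
        self.pitch = pitch
        self.quantum = quantum_um
        self._cache: dict[int, np.ndarray] = {}

    def stamp(self, volume: np.ndarray, center_idx: np.ndarray, radius_um: float):
        q = max(1, int(round(radius_um / self.quantum)))
        offs = self._cache.get(q)
        if offs is None:
            offs = self._cache[q] = _ball_offsets(q * self.quantum, self.pitch)
        pts = center_idx[None, :] + offs
        ok = np.all((pts >= 0) & (pts < self.shape[None, :]), axis=1)
        pts = pts[ok]
        volume[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def _grow_stratum(rng, spec: PhantomSpec, start_xy, bounds_um):
    """Random branching walk in the plane; returns polyline segments.

    Each segment is (parent_xy, child_xy, path_len_at_child).  Direction
    persistence and a per-step branching probability give a plausible
    space-filling dendritic field with controllable total length.
    """
    segments = []
    theta0 = rng.uniform(0, 2 * np.pi)
    n_init = 4
    tips = []
    for k in range(n_init):
        ang = theta0 + 2 * np.pi * k / n_init + rng.normal(0, 0.3)
        tips.append((np.asarray(start_xy, float), np.array([np.cos(ang), np.sin(ang)]), 0.0))
    total = 0.0
    lo, hi = bounds_um
    while tips and total < spec.stratum_length_um:
        xy, d, plen = tips.pop(rng.integers(len(tips)))
        turn = rng.normal(0, 1.0, size=2)
        d = spec.persistence * d + (1 - spec.persistence) * turn
        d /= np.linalg.norm(d) + 1e-12
        nxt = xy + spec.step_um * d
        if np.any(nxt < lo) or np.any(nxt > hi):
            continue  # branch terminates at the field border
        plen2 = plen + spec.step_um
        segments.append((xy, nxt, plen2))
        total += spec.step_um
        tips.append((nxt, d, plen2))
        if rng.random() < spec.branch_prob:
            ang = rng.uniform(np.pi / 6, np.pi / 2) * rng.choice([-1, 1])
            c, s = np.cos(ang), np.sin(ang)
            db = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
            tips.append((nxt, db, plen2))
    return segments


def _lamina_height(spec: PhantomSpec, phases, x_um, y_um):
    """True On-lamina height (μm) at in-plane positions."""
    k = 2 * np.pi / spec.warp_wavelength_um
    return spec.on_base_um + spec.warp_amplitude_um * np.sin(
        k * x_um + phases[0]) * np.cos(k * y_um + phases[1])


def make_phantom(spec: PhantomSpec) -> tuple[ImageStack, ImageStack, PhantomTruth]:
    """Render one phantom: neuron channel, fiducial channel, ground truth.

    All randomness derives from ``spec.seed``; identical specs render
    bitwise-identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    grid = VoxelGrid(spec.shape, spec.pitch)
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.pitch
    phases = rng.uniform(0, 2 * np.pi, size=2)

    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    z_on = _lamina_height(spec, phases, X, Y)
    z_off = z_on + OFF_DEPTH_UM

    depths = TYPE_DEPTHS_UM[spec.cell_type]
    offsets = tuple(float(rng.normal(0.0, spec.jitter_um)) for _ in depths)

    margin = 8.0
    center_xy = np.array([xs[-1] / 2, ys[-1] / 2]) + rng.uniform(-8, 8, size=2)
    bounds = (np.array([margin, margin]), np.array([xs[-1] - margin, ys[-1] - margin]))

    stamper = _Stamper(spec.shape, spec.pitch)
    tube = np.zeros(spec.shape, dtype=bool)
    arbor = np.zeros(spec.shape, dtype=bool)

    def on_height_at(xy):
        return _lamina_height(spec, phases, xy[..., 0], xy[..., 1])

    nodes: list[SkeletonNode] = []
    nid = 1

    # soma + primary dendrite (trunk) from the soma up through the strata
    soma_z = float(on_height_at(center_xy[None, :])[0]) + spec.soma_depth_um
    soma_idx = grid.to_index(np.array([*center_xy, soma_z]))
    stamper.stamp(tube, soma_idx, spec.soma_diameter_um / 2)
    nodes.append(SkeletonNode(nid, 1, center_xy[0], center_xy[1], soma_z,
                              spec.soma_diameter_um / 2, -1))
    soma_id = nid
    nid += 1

    trunk_top = float(on_height_at(center_xy[None, :])[0]) + max(depths) + offsets[-1]
    zline = np.arange(soma_z, trunk_top, 0.35)
    prev = soma_id
    for zv in zline[1:]:
        stamper.stamp(tube, grid.to_index(np.array([*center_xy, zv])), 0.8)
        nodes.append(SkeletonNode(nid, 3, center_xy[0], center_xy[1], float(zv), 0.8, prev))
        prev = nid
        nid += 1
    trunk_id = prev

    stratum_masks: list[np.ndarray] = []
    for depth, offset in zip(depths, offsets):
        segments = _grow_stratum(rng, spec, center_xy, bounds)
        max_len = max((s[2] for s in segments), default=1.0)
        seg_parent: dict[tuple, int] = {tuple(np.round(center_xy, 6)): trunk_id}
        smask = np.zeros(spec.shape, dtype=bool)
        for a, b, plen in segments:
            frac = plen / max_len
            radius = spec.radius_root_um + (spec.radius_tip_um - spec.radius_root_um) * frac
            # sample densely along the segment; z follows the wavy lamina
            npts = max(2, int(np.ceil(spec.step_um / 0.3)) + 1)
            t = np.linspace(0, 1, npts)[:, None]
            pts_xy = a[None, :] * (1 - t) + b[None, :] * t
            z = on_height_at(pts_xy) + depth + offset
            pts = np.column_stack([pts_xy, z])
            idx = grid.to_index(pts)
            for p in idx:
                stamper.stamp(smask, p, radius)
            pid = seg_parent.get(tuple(np.round(a, 6)), trunk_id)
            nodes.append(SkeletonNode(nid, 3, float(b[0]), float(b[1]),
                                      float(z[-1]), radius, pid))
            seg_parent[tuple(np.round(b, 6))] = nid
            nid += 1
        arbor |= smask
        stratum_masks.append(smask)

    tube |= arbor
    skeleton = Skeleton(nodes)

    # per-voxel truth depth: the stratification depth of the centerline that
    # stamped the voxel (depth is measured from the local On-lamina height,
    # so it is constant per stratum by construction)
    parts = []
    for smask, depth, offset in zip(stratum_masks, depths, offsets):
        parts.append(np.full(int(smask.sum()), depth + offset))
    arbor_depths = np.concatenate(parts) if parts else np.empty(0)

    blur_vox = tuple(s / p for s, p in zip(spec.blur_sigma_um, spec.pitch))

    def render(clean: np.ndarray) -> np.ndarray:
        img = ndimage.gaussian_filter(clean.astype(np.float32), blur_vox)
        img *= spec.peak_photons / max(float(img.max()), 1e-9)
        noisy = rng.poisson(img).astype(np.float32)
        noisy += rng.normal(0, spec.read_noise_frac * spec.peak_photons,
                            size=img.shape).astype(np.float32)
        return np.clip(noisy, 0, None)

    neuron = ImageStack(grid, render(tube), role="neuron")

    zcol = (np.arange(nz) * dz)[None, None, :]
    sigma_l = 0.8  # μm; starburst plexus half-thickness
    sheets = (np.exp(-((zcol - z_on[..., None]) ** 2) / (2 * sigma_l ** 2))
              + np.exp(-((zcol - z_off[..., None]) ** 2) / (2 * sigma_l ** 2)))
    chat_img = sheets.astype(np.float32) * spec.peak_photons
    chat_noisy = rng.poisson(chat_img).astype(np.float32)
    chat_noisy += rng.normal(0, spec.read_noise_frac * spec.peak_photons,
                             size=chat_img.shape).astype(np.float32)
    chat = ImageStack(grid, np.clip(chat_noisy, 0, None), role="fiducial")

    all_valid = np.ones((nx, ny), dtype=bool)
    truth = PhantomTruth(
        skeleton=skeleton,
        true_volume=BinaryVolume(grid, tube),
        surfaces=(
            Surface(z_on, all_valid, "On", (dx, dy)),
            Surface(z_off, all_valid, "Off", (dx, dy)),
        ),
        arbor_depths_um=arbor_depths,
        arbor_mask=arbor,
        stratum_offsets_um=offsets,
    )
    return neuron, chat, truth


def add_distractors(
    neuron: ImageStack,
    truth: PhantomTruth,
    count: int,
    seed: int = 0,
    min_clearance_um: float = 20.0,
) -> ImageStack:
    """Add disconnected bright blobs and neurite fragments to the stack.

    Every distractor center keeps at least ``min_clearance_um`` from the
    true structure and from other distractors, so each appears as its own
    connected component after thresholding.  Ground truth is unchanged.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return ImageStack(neuron.grid, neuron.values.copy(), role=neuron.role)
    rng = np.random.default_rng(seed)
    grid = neuron.grid
    pitch = np.asarray(grid.pitch)
    shape = np.asarray(grid.shape)
    true_idx = np.argwhere(truth.true_volume.mask)
    from scipy.spatial import cKDTree

    tree = cKDTree(true_idx[:: max(1, len(true_idx) // 20000)] * pitch)
    placed_pts: list[np.ndarray] = []
    extra = np.zeros(grid.shape, dtype=bool)
    stamper = _Stamper(grid.shape, grid.pitch)
    attempts = 0
    n_placed = 0
    while n_placed < count and attempts < 2000:
        attempts += 1
        pos = rng.uniform([10, 10, 5], shape * pitch - [10, 10, 5])
        if rng.random() < 0.5:  # blob (stray soma fragment)
            pts = pos[None, :]
            radius = float(rng.uniform(1.5, 2.5))
        else:  # short neurite fragment, thick enough to survive the PSF
            d = rng.normal(size=3)
            d[2] *= 0.2
            d /= np.linalg.norm(d)
            ts = np.arange(0, rng.uniform(8, 15), 0.3)
            pts = pos[None, :] + ts[:, None] * d[None, :]
            inside = np.all((pts > 2) & (pts < shape * pitch - 2), axis=1)
            pts = pts[inside]
            radius = 1.2
        if len(pts) == 0:
            continue
        # the whole object must keep clear of the neuron and of every
        # previously placed distractor, so components stay disconnected
        if tree.query(pts)[0].min() < min_clearance_um:
            continue
        if placed_pts:
            prev = np.vstack(placed_pts)
            if cKDTree(prev).query(pts)[0].min() < 8.0:
                continue
        placed_pts.append(pts)
        for p in pts:
            stamper.stamp(extra, grid.to_index(p), radius)
        n_placed += 1
    if n_placed < count:
        raise RuntimeError("could not place all distractors with the required clearance")

    blur_vox = tuple(0.3 / p for p in grid.pitch[:2]) + (0.6 / grid.pitch[2],)
    img = ndimage.gaussian_filter(extra.astype(np.float32), blur_vox)
    # scale each distractor individually so thin fragments are as visible
    # as blobs after the PSF, while the combined intensity never exceeds
    # the stack's original peak (the global threshold must not move)
    peak = float(neuron.values.max())
    support = ndimage.binary_dilation(extra, iterations=4)
    labels, n = ndimage.label(support)
    for lbl in range(1, n + 1):
        region = labels == lbl
        local_max = float(img[region].max())
        local_bg = float(neuron.values[region].max())
        if local_max > 0:
            img[region] *= (peak - local_bg) / local_max
    return ImageStack(grid, neuron.values + img, role=neuron.role)
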
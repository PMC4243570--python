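"""Fiducial-surface detection, quasi-conformal flattening, and unwarping.

The two starburst (ChAT) laminae serve as fiducial surfaces.  Each is
detected as a height map over the in-plane grid, triangulated, and
flattened by a least-squares conformal map (minimizing angle distortion).
The two flattened surfaces are registered in-plane at the patch where both
laminae are flattest, the mapping is extended to all voxels by local
polynomial models (quadratic in xy, linear in z), and depth is normalized
per column so the On surface sits at 0 μm and the Off surface at 12 μm,
with linear extrapolation beyond them.  Depth increases toward the inner
nuclear layer, so the ganglion-cell side is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .volio import BinaryVolume, ImageStack, VoxelGrid

__all__ = [
    "Surface",
    "ConformalMap",
    "WarpField",
    "OFF_DEPTH_UM",
    "detect_surfaces",
    "flatten_lscm",
    "conformal_energy",
    "register_inplane",
    "build_warp",
    "harmonic_fill",
]

OFF_DEPTH_UM = 12.0  # fixed depth convention for the Off starburst surface


class DetectionError(RuntimeError):
    """Fewer than two usable laminae in the fiducial channel."""


@dataclass
class Surface:
    """Height map z(x, y) in μm over the in-plane grid.

    ``valid`` flags nodes whose height came from a detected peak (invalid
    nodes are filled by harmonic interpolation but carry no evidence).
    """

    heights: np.ndarray          # (nx, ny) μm
    valid: np.ndarray            # (nx, ny) bool
    label: str                   # "On" | "Off"
    pitch_xy: tuple[float, float] = (0.4, 0.4)
    origin_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.heights.shape != self.valid.shape:
            raise ValueError("heights and valid must share a shape")
        if not np.all(np.isfinite(self.heights[self.valid])):
            raise ValueError("heights must be finite where valid")

    def node_xy(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.heights.shape
        xs = self.origin_xy[0] + np.arange(nx) * self.pitch_xy[0]
        ys = self.origin_xy[1] + np.arange(ny) * self.pitch_xy[1]
        return xs, ys

    def interpolator(self) -> RegularGridInterpolator:
        xs, ys = self.node_xy()
        return RegularGridInterpolator(
            (xs, ys), self.heights, bounds_error=False, fill_value=None
        )


# ---------------------------------------------------------------------------
# Surface detection


def harmonic_fill(heights: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid nodes by solving the discrete Laplace equation.

    Valid nodes are Dirichlet data; grid edges get natural (no-flux)
    boundary conditions.
    """
    if valid.all():
        return heights.copy()
    if not valid.any():
        raise ValueError("cannot fill a fully invalid height map")
    nx, ny = heights.shape
    idx = -np.ones((nx, ny), dtype=np.int64)
    unknown = np.argwhere(~valid)
    idx[~valid] = np.arange(len(unknown))
    rows, cols, vals = [], [], []
    b = np.zeros(len(unknown))
    for r, (i, j) in enumerate(unknown):
        deg = 0
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if not (0 <= ii < nx and 0 <= jj < ny):
                continue
            deg += 1
            if valid[ii, jj]:
                b[r] += heights[ii, jj]
            else:
                rows.append(r)
                cols.append(idx[ii, jj])
                vals.append(-1.0)
        rows.append(r)
        cols.append(r)
        vals.append(float(deg))
    A = sparse.csc_matrix((vals, (rows, cols)), shape=(len(unknown), len(unknown)))
    x = spsolve(A, b)
    out = heights.copy()
    out[~valid] = x
    return out


def detect_surfaces(
    chat: ImageStack,
    smooth_sigma: float = 1.0,
    min_separation_um: float = 6.0,
    mad_factor: float = 3.0,
) -> tuple[Surface, Surface]:
    """Detect the On and Off starburst laminae as height maps.

    Per (x, y) column of the Gaussian-smoothed fiducial stack, the two
    strongest intensity peaks along z (at least ``min_separation_um``
    apart) become height samples, refined to sub-voxel precision by
    parabolic interpolation.  Samples deviating more than ``mad_factor``
    median absolute deviations from a median-filtered height map are
    invalidated, and gaps are filled harmonically.  The surface at smaller
    z (ganglion-cell side) is labeled On.
    """
    dx, dy, dz = chat.grid.pitch
    v = ndimage.gaussian_filter(np.asarray(chat.values, dtype=float), smooth_sigma)
    nx, ny, nz = v.shape
    if nz < 5:
        raise DetectionError("stack too shallow for lamina detection")

    # strict/weak comparison resolves plateaus to a single local maximum
    interior = v[:, :, 1:-1]
    locmax = (interior > v[:, :, :-2]) & (interior >= v[:, :, 2:])
    peakval = np.full_like(v, -np.inf)
    peakval[:, :, 1:-1] = np.where(locmax, interior, -np.inf)

    k1 = np.argmax(peakval, axis=2)
    v1 = np.take_along_axis(peakval, k1[..., None], axis=2)[..., 0]

    sep = max(1, int(round(min_separation_um / dz)))
    zidx = np.arange(nz)[None, None, :]
    masked = np.where(np.abs(zidx - k1[..., None]) >= sep, peakval, -np.inf)
    k2 = np.argmax(masked, axis=2)
    v2 = np.take_along_axis(masked, k2[..., None], axis=2)[..., 0]

    # a usable second peak must rise meaningfully above the stack floor
    floor = 0.1 * float(v.max())
    ok = np.isfinite(v1) & np.isfinite(v2) & (v1 > floor) & (v2 > floor)
    if ok.mean() < 0.5:
        raise DetectionError(
            f"two laminae detectable in only {100 * ok.mean():.0f}% of columns"
        )

    def refine(k):
        k = np.clip(k, 1, nz - 2)
        c = np.take_along_axis(v, k[..., None], axis=2)[..., 0]
        l = np.take_along_axis(v, (k - 1)[..., None], axis=2)[..., 0]
        r = np.take_along_axis(v, (k + 1)[..., None], axis=2)[..., 0]
        denom = l - 2 * c + r
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (l - r) / np.where(denom == 0, 1, denom), 0.0)
        return k + np.clip(shift, -0.5, 0.5)

    zlo = np.minimum(refine(k1), refine(k2)) * dz + chat.grid.origin[2]
    zhi = np.maximum(refine(k1), refine(k2)) * dz + chat.grid.origin[2]

    def clean(h, valid):
        med = ndimage.median_filter(h, size=5)
        dev = np.abs(h - med)
        mad = np.median(dev[valid]) if valid.any() else 0.0
        # floor at a tenth of the axial pitch: sub-voxel scatter is noise,
        # not evidence of a mis-picked peak
        good = valid & (dev <= mad_factor * mad + 0.1 * dz)
        if not good.any():
            good = valid
        filled = harmonic_fill(np.where(good, h, 0.0), good)
        return filled, good

    h_on, ok_on = clean(zlo, ok)
    h_off, ok_off = clean(zhi, ok)
    both = ok_on & ok_off
    if both.any() and not np.all(h_on[both] < h_off[both]):
        raise DetectionError("surface ordering violated (On must lie below Off in z)")

    pxy = (dx, dy)
    oxy = (chat.grid.origin[0], chat.grid.origin[1])
    return (
        Surface(h_on, ok_on, "On", pxy, oxy),
        Surface(h_off, ok_off, "Off", pxy, oxy),
    )


# ---------------------------------------------------------------------------
# Least-squares conformal flattening


@dataclass
class ConformalMap:
    """Triangulated surface with planar (u, v) coordinates per vertex."""

    vertices: np.ndarray         # (n, 3) μm
    triangles: np.ndarray        # (m, 3) int
    uv: np.ndarray               # (n, 2) μm
    energy: float                # summed per-triangle conformal energy
    grid_shape: tuple[int, int]  # mesh node grid (gnx, gny)
    xs: np.ndarray               # (gnx,) node x coordinates, μm
    ys: np.ndarray               # (gny,) node y coordinates, μm
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def uv_at(self, xy: np.ndarray) -> np.ndarray:
        """Registered planar image of in-plane points (..., 2), μm."""
        u = RegularGridInterpolator(
            (self.xs, self.ys), self.uv[:, 0].reshape(self.grid_shape),
            bounds_error=False, fill_value=None)
        v = RegularGridInterpolator(
            (self.xs, self.ys), self.uv[:, 1].reshape(self.grid_shape),
            bounds_error=False, fill_value=None)
        xy = np.asarray(xy, dtype=float)
        out = np.stack([u(xy), v(xy)], axis=-1)
        return out + self.offset

    def with_offset(self, offset) -> "ConformalMap":
        return ConformalMap(self.vertices, self.triangles, self.uv, self.energy,
                            self.grid_shape, self.xs, self.ys,
                            self.offset + np.asarray(offset, dtype=float))


def _triangle_gradients(p3: np.ndarray):
    """Per-triangle local frames: areas and shape-function gradients.

    Returns (areas (m,), Gx (m,3), Gy (m,3)) where the gradient of the
    linear basis function of vertex j inside triangle t is
    (Gx[t, j], Gy[t, j]) in the triangle's local orthonormal frame.
    """
    e1 = p3[:, 1] - p3[:, 0]
    e2 = p3[:, 2] - p3[:, 0]
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n, axis=1)
    if np.any(nn < 1e-15):
        raise ValueError("degenerate mesh triangle")
    a1 = np.linalg.norm(e1, axis=1)
    u1 = e1 / a1[:, None]
    w = n / nn[:, None]
    u2 = np.cross(w, u1)
    # local 2-D coords: q0 = (0,0), q1 = (|e1|, 0), q2 = (e2.u1, e2.u2)
    q = np.zeros((len(p3), 3, 2))
    q[:, 1, 0] = a1
    q[:, 2, 0] = np.einsum("ij,ij->i", e2, u1)
    q[:, 2, 1] = np.einsum("ij,ij->i", e2, u2)
    areas = 0.5 * q[:, 1, 0] * q[:, 2, 1]
    # grad of basis j = perp(edge opposite j) / (2A), perp = CCW rotate
    Gx = np.empty((len(p3), 3))
    Gy = np.empty((len(p3), 3))
    for j in range(3):
        opp = q[:, (j + 2) % 3] - q[:, (j + 1) % 3]
        Gx[:, j] = -opp[:, 1] / (2 * areas)
        Gy[:, j] = opp[:, 0] / (2 * areas)
    return areas, Gx, Gy


def conformal_energy(vertices: np.ndarray, triangles: np.ndarray, uv: np.ndarray) -> float:
    """Summed conformal (angle-distortion) energy of a parameterization.

    E = Σ_T A_T |∂f/∂z̄|² with f = u + iv over local triangle coordinates;
    zero iff the map is conformal on every triangle.
    """
    p3 = vertices[triangles]
    areas, Gx, Gy = _triangle_gradients(p3)
    u = uv[triangles, 0]
    v = uv[triangles, 1]
    ux = np.einsum("tj,tj->t", Gx, u)
    uy = np.einsum("tj,tj->t", Gy, u)
    vx = np.einsum("tj,tj->t", Gx, v)
    vy = np.einsum("tj,tj->t", Gy, v)
    return float(np.sum(areas * 0.25 * ((ux - vy) ** 2 + (uy + vx) ** 2)))


def _mesh_from_surface(s: Surface, max_vertices: int):
    nx, ny = s.heights.shape
    stride = 1
    while (len(range(0, nx, stride)) * len(range(0, ny, stride))) > max_vertices:
        stride += 1
    xi = np.arange(0, nx, stride)
    yi = np.arange(0, ny, stride)
    if xi[-1] != nx - 1:
        xi = np.append(xi, nx - 1)
    if yi[-1] != ny - 1:
        yi = np.append(yi, ny - 1)
    xs = s.origin_xy[0] + xi * s.pitch_xy[0]
    ys = s.origin_xy[1] + yi * s.pitch_xy[1]
    H = s.heights[np.ix_(xi, yi)]
    gnx, gny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), H.ravel()])
    node = np.arange(gnx * gny).reshape(gnx, gny)
    a = node[:-1, :-1].ravel()
    b = node[1:, :-1].ravel()
    c = node[:-1, 1:].ravel()
    d = node[1:, 1:].ravel()
    triangles = np.concatenate(
        [np.column_stack([a, b, d]), np.column_stack([a, d, c])]
    )
    return vertices, triangles, (gnx, gny), xs, ys


def flatten_lscm(s: Surface, max_vertices: int = 10_000) -> ConformalMap:
    """Least-squares conformal parameterization of a lamina height map.

    The gauge is fixed by pinning two mutually distant boundary vertices
    at planar positions (0, 0) and (D, 0), D being their 3-D distance, so
    a developable (e.g., planar) surface maps isometrically.
    """
    # scattered invalid nodes (outlier rejection) are fine; refuse only a
    # domain whose detected evidence is split into disjoint patches
    lab, n4 = ndimage.label(s.valid, structure=ndimage.generate_binary_structure(2, 2))
    if n4 == 0:
        raise ValueError("surface has no valid nodes")
    if n4 > 1:
        sizes = np.bincount(lab.ravel())[1:]
        if sizes.max() < 0.75 * s.valid.sum():
            raise ValueError("valid region of the surface is disconnected")
    vertices, triangles, gshape, xs, ys = _mesh_from_surface(s, max_vertices)
    nv = len(vertices)
    areas, Gx, Gy = _triangle_gradients(vertices[triangles])

    # residual rows: r_re = 1/2 sqrt(A) (u_x - v_y); r_im = 1/2 sqrt(A) (u_y + v_x)
    m = len(triangles)
    sq = 0.5 * np.sqrt(areas)
    rows, cols, vals = [], [], []
    for j in range(3):
        tj = triangles[:, j]
        r = np.arange(m)
        rows += [r, r, r + m, r + m]
        cols += [tj, tj + nv, tj, tj + nv]
        vals += [sq * Gx[:, j], -sq * Gy[:, j], sq * Gy[:, j], sq * Gx[:, j]]
    M = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(2 * m, 2 * nv),
    )

    # pin two mutually distant boundary vertices (opposite grid corners)
    gnx, gny = gshape
    p0 = 0
    p1 = gnx * gny - 1
    D = float(np.linalg.norm(vertices[p1] - vertices[p0]))
    pinned = np.array([p0, p0 + nv, p1, p1 + nv])
    pin_vals = np.array([0.0, 0.0, D, 0.0])

    free = np.setdiff1d(np.arange(2 * nv), pinned)
    Mf = M[:, free]
    rhs = -M[:, pinned] @ pin_vals
    A = (Mf.T @ Mf).tocsc()
    x_free = spsolve(A, Mf.T @ rhs)
    x = np.zeros(2 * nv)
    x[free] = x_free
    x[pinned] = pin_vals
    uv = np.column_stack([x[:nv], x[nv:]])

    # fix global orientation so planar triangle areas are positive
    u3 = uv[triangles]
    signed = 0.5 * (
        (u3[:, 1, 0] - u3[:, 0, 0]) * (u3[:, 2, 1] - u3[:, 0, 1])
        - (u3[:, 2, 0] - u3[:, 0, 0]) * (u3[:, 1, 1] - u3[:, 0, 1])
    )
    if np.sum(signed < 0) > np.sum(signed > 0):
        uv[:, 1] *= -1.0

    energy = conformal_energy(vertices, triangles, uv)
    return ConformalMap(vertices, triangles, uv, energy, gshape, xs, ys)


# ---------------------------------------------------------------------------
# In-plane registration


def _flattest_window_center(on: Surface, off: Surface, window_um: float):
    """Center (x, y) μm of the flattest window over both height maps.

    Flatness of a window is the summed height variance of both surfaces
    over its valid nodes; ties break toward the smallest (x, y).
    """
    xs, ys = on.node_xy()
    wx = max(2, int(round(window_um / on.pitch_xy[0])))
    wy = max(2, int(round(window_um / on.pitch_xy[1])))
    nx, ny = on.heights.shape
    if wx > nx or wy > ny:
        raise ValueError("flatness window larger than the surface grid")
    sx, sy = max(1, wx // 2), max(1, wy // 2)

    best = None
    best_center = None
    for i0 in range(0, nx - wx + 1, sx):
        for j0 in range(0, ny - wy + 1, sy):
            score = 0.0
            usable = True
            for surf in (on, off):
                hw = surf.heights[i0:i0 + wx, j0:j0 + wy]
                vw = surf.valid[i0:i0 + wx, j0:j0 + wy]
                if vw.sum() < 4:
                    usable = False
                    break
                score += float(np.var(hw[vw]))
            if not usable:
                continue
            if best is None or score < best - 1e-15:
                best = score
                best_center = (xs[i0] + (wx - 1) * on.pitch_xy[0] / 2,
                               ys[j0] + (wy - 1) * on.pitch_xy[1] / 2)
    if best is None:
        raise ValueError("no usable flatness window")
    return best_center


def register_inplane(
    on_map: ConformalMap,
    off_map: ConformalMap,
    on: Surface,
    off: Surface,
    window_um: float = 32.0,
) -> tuple[float, float]:
    """Planar offset aligning the two flattened laminae.

    The anchor is the flattest window (side ``window_um``, stride half a
    window) over both height maps.  The returned (du, dv), added to the
    Off map, makes the two flattened images of the anchor center coincide.
    """
    center = np.asarray(_flattest_window_center(on, off, window_um))
    uv_on = on_map.uv_at(center[None, :])
    uv_off = off_map.uv_at(center[None, :])
    delta = (uv_on - uv_off).ravel()
    return float(delta[0]), float(delta[1])


# ---------------------------------------------------------------------------
# Extension of the mapping to all voxels


@dataclass
class WarpField:
    """Per-voxel mapping to flattened coordinates (u, v, depth).

    ``transform`` evaluates the mapping at voxel indices; the volume
    compensation weight is |det J| of the (x, y, z) → (u, v, depth) map,
    estimated by central finite differences on a coarse lattice.
    """

    grid: VoxelGrid
    _u_interp: RegularGridInterpolator
    _v_interp: RegularGridInterpolator
    _w_interp: RegularGridInterpolator
    _z_on: RegularGridInterpolator
    _z_off: RegularGridInterpolator

    def transform(self, indices: np.ndarray):
        """Map (n, 3) voxel indices to (u, v, depth, weight) arrays (μm)."""
        xyz = self.grid.to_physical(np.asarray(indices, dtype=float))
        return self.transform_physical(xyz)

    def transform_physical(self, xyz: np.ndarray):
        xy = xyz[:, :2]
        z_on = self._z_on(xy)
        z_off = self._z_off(xy)
        span = np.maximum(z_off - z_on, 1e-9)
        depth = OFF_DEPTH_UM * (xyz[:, 2] - z_on) / span
        pts = xyz
        u = self._u_interp(pts)
        v = self._v_interp(pts)
        w = np.maximum(np.abs(self._w_interp(pts)), 1e-12)
        return u, v, depth, w

    def points_for_mask(self, volume: BinaryVolume):
        """(u, v, depth, weight) for every foreground voxel of a mask."""
        idx = np.argwhere(volume.mask)
        return idx, self.transform(idx)


def _local_polynomial_uv(corr_xyz, corr_uv, X, Y, z_levels, radius, tree):
    """WLS fit of (u, v) at one in-plane lattice node; returns (nz, 2)."""
    for attempt, r in enumerate((radius, 2 * radius)):
        sel = tree.query_ball_point([X, Y], r)
        if len(sel) >= 12:
            P = corr_xyz[sel]
            Q = corr_uv[sel]
            dxy = P[:, :2] - [X, Y]
            d2 = np.sum(dxy ** 2, axis=1)
            w = np.exp(-d2 / (2 * (r / 2) ** 2))
            dx, dy, z = dxy[:, 0], dxy[:, 1], P[:, 2]
            A = np.column_stack([np.ones_like(dx), dx, dy, dx**2, dx*dy, dy**2, z, dx*z, dy*z])
            Aw = A * w[:, None]
            gram = A.T @ Aw
            if np.linalg.cond(gram) < 1e10:
                coef = np.linalg.solve(gram, Aw.T @ Q)  # (9, 2)
                basis = np.column_stack([
                    np.ones_like(z_levels), np.zeros_like(z_levels), np.zeros_like(z_levels),
                    np.zeros_like(z_levels), np.zeros_like(z_levels), np.zeros_like(z_levels),
                    z_levels, np.zeros_like(z_levels), np.zeros_like(z_levels),
                ])
                return basis @ coef
    raise ValueError(
        f"rank-deficient local fit at ({X:.1f}, {Y:.1f}) even after doubling the radius"
    )


def build_warp(
    on_map: ConformalMap,
    off_map: ConformalMap,
    on: Surface,
    off: Surface,
    grid: VoxelGrid,
    fit_radius_um: float = 25.0,
    lattice_spacing_um: float = 6.0,
    n_z_levels: int = 5,
) -> WarpField:
    """Extend the surface flattening to every voxel of the stack.

    Correspondence points are the mesh nodes of both flattened surfaces
    (the Off map is expected to carry its registration offset).  At each
    node of a coarse in-plane lattice, (u, v) is modeled by weighted least
    squares over monomials (1, x, y, x², xy, y², z, xz, yz) of the
    correspondence points within ``fit_radius_um`` (Gaussian weights,
    σ = half the radius); voxel values are interpolated from the lattice.
    Depth is the per-column affine map sending the On surface to 0 μm and
    the Off surface to 12 μm.
    """
    corr_xyz = np.vstack([on_map.vertices, off_map.vertices])
    corr_uv = np.vstack([on_map.uv + on_map.offset, off_map.uv + off_map.offset])
    tree = cKDTree(corr_xyz[:, :2])

    dx, dy, dz = grid.pitch
    ox, oy, oz = grid.origin
    ext_x = (grid.shape[0] - 1) * dx
    ext_y = (grid.shape[1] - 1) * dy
    ext_z = (grid.shape[2] - 1) * dz
    lx = np.linspace(ox, ox + ext_x, max(3, int(ext_x / lattice_spacing_um) + 1))
    ly = np.linspace(oy, oy + ext_y, max(3, int(ext_y / lattice_spacing_um) + 1))
    lz = np.linspace(oz, oz + ext_z, max(3, n_z_levels))

    U = np.empty((len(lx), len(ly), len(lz)))
    V = np.empty_like(U)
    for i, X in enumerate(lx):
        for j, Y in enumerate(ly):
            uv = _local_polynomial_uv(corr_xyz, corr_uv, X, Y, lz, fit_radius_um, tree)
            U[i, j] = uv[:, 0]
            V[i, j] = uv[:, 1]

    xs_s, ys_s = on.node_xy()
    z_on_i = RegularGridInterpolator((xs_s, ys_s), on.heights,
                                     bounds_error=False, fill_value=None)
    z_off_i = RegularGridInterpolator((xs_s, ys_s), off.heights,
                                      bounds_error=False, fill_value=None)

    # depth field on the lattice for the Jacobian estimate
    LX, LY, LZ = np.meshgrid(lx, ly, lz, indexing="ij")
    pts2 = np.column_stack([LX.ravel(), LY.ravel()])
    zo = z_on_i(pts2).reshape(LX.shape)
    zf = z_off_i(pts2).reshape(LX.shape)
    Dp = OFF_DEPTH_UM * (LZ - zo) / np.maximum(zf - zo, 1e-9)

    def grad3(F):
        return np.gradient(F, lx, ly, lz, edge_order=1)

    ux, uy, uz = grad3(U)
    vx, vy, vz = grad3(V)
    dxg, dyg, dzg = grad3(Dp)
    det = (ux * (vy * dzg - vz * dyg)
           - uy * (vx * dzg - vz * dxg)
           + uz * (vx * dyg - vy * dxg))
    W = np.abs(det)

    interp = lambda F: RegularGridInterpolator((lx, ly, lz), F,
                                               bounds_error=False, fill_value=None)
    return WarpField(grid, interp(U), interp(V), interp(W), z_on_i, z_off_i)
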
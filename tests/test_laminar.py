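"""Surface detection, conformal flattening, registration, warp fields."""

import numpy as np
import pytest

from arbordepth.laminar import (
    ConformalMap,
    DetectionError,
    Surface,
    build_warp,
    conformal_energy,
    detect_surfaces,
    flatten_lscm,
    harmonic_fill,
    register_inplane,
)
from arbordepth.volio import ImageStack, VoxelGrid


def _chat_stack(z_on, z_off, shape=(48, 48, 80), pitch=(0.4, 0.4, 0.5),
                sigma_um=0.8, noise=0.0, seed=0):
    """Fiducial stack with two Gaussian-profile laminae at given heights."""
    nx, ny, nz = shape
    zcol = (np.arange(nz) * pitch[2])[None, None, :]
    img = (np.exp(-((zcol - z_on[..., None]) ** 2) / (2 * sigma_um**2))
           + np.exp(-((zcol - z_off[..., None]) ** 2) / (2 * sigma_um**2)))
    img *= 1000.0
    if noise:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise * 1000.0, size=img.shape)
    return ImageStack(VoxelGrid(shape, pitch), np.clip(img, 0, None), role="fiducial")


def _flat_heights(shape, value):
    return np.full(shape, float(value))


class TestDetectSurfaces:
    def test_flat_noiseless_laminae_recovered_exactly(self):
        shape = (32, 32, 64)
        z_on = _flat_heights(shape[:2], 20 * 0.5)
        z_off = _flat_heights(shape[:2], 44 * 0.5)
        on, off = detect_surfaces(_chat_stack(z_on, z_off, shape))
        assert np.allclose(on.heights, 10.0, atol=1e-6)
        assert np.allclose(off.heights, 22.0, atol=1e-6)
        assert on.label == "On" and off.label == "Off"

    def test_wavy_noisy_laminae_within_half_micron(self):
        shape = (64, 64, 80)
        xs = np.arange(shape[0]) * 0.4
        ys = np.arange(shape[1]) * 0.4
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        z_on = 12.0 + 4.0 * np.sin(2 * np.pi * X / 100) * np.cos(2 * np.pi * Y / 100)
        z_off = z_on + 12.0
        # SNR 10: noise SD is a tenth of the lamina peak amplitude
        on, off = detect_surfaces(_chat_stack(z_on, z_off, shape, noise=0.1, seed=1))
        assert np.sqrt(np.mean((on.heights - z_on) ** 2)) < 0.5
        assert np.sqrt(np.mean((off.heights - z_off) ** 2)) < 0.5

    def test_single_lamina_fails(self):
        shape = (24, 24, 60)
        z = _flat_heights(shape[:2], 15.0)
        img = _chat_stack(z, z, shape)  # both sheets coincide: one lamina
        with pytest.raises(DetectionError):
            detect_surfaces(img)


def test_harmonic_fill_interpolates_linear_fields_exactly():
    # a harmonic (here linear) field is reproduced through arbitrary holes
    nx, ny = 20, 16
    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                       indexing="ij")
    h = 2.0 + 0.3 * X - 0.1 * Y
    valid = np.ones((nx, ny), bool)
    valid[5:9, 4:10] = False
    filled = harmonic_fill(np.where(valid, h, 0.0), valid)
    assert np.allclose(filled, h, atol=1e-8)


def _surface(h, pitch=(1.0, 1.0)):
    return Surface(h, np.ones(h.shape, bool), "On", pitch)


class TestFlattenLscm:
    def test_planar_surface_maps_rigidly(self):
        m = flatten_lscm(_surface(_flat_heights((30, 24), 7.0)))
        assert m.energy < 1e-8
        rng = np.random.default_rng(0)
        idx = rng.integers(0, len(m.vertices), size=(60, 2))
        d3 = np.linalg.norm(m.vertices[idx[:, 0]] - m.vertices[idx[:, 1]], axis=1)
        d2 = np.linalg.norm(m.uv[idx[:, 0]] - m.uv[idx[:, 1]], axis=1)
        assert np.allclose(d2, d3, rtol=1e-6, atol=1e-6)

    def test_energy_matches_independent_evaluation(self):
        # hemisphere-like cap; recompute the conformal energy from its
        # definition with an independent per-triangle least-squares fit
        n = 24
        xs = np.linspace(-1, 1, n)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        h = 8.0 * np.sqrt(np.clip(2.0 - X**2 - Y**2, 0.5, None))
        m = flatten_lscm(_surface(h, (2.0 / (n - 1), 2.0 / (n - 1))))

        total = 0.0
        for tri in m.triangles:
            p = m.vertices[tri]
            q = m.uv[tri]
            e1 = p[1] - p[0]
            e2 = p[2] - p[0]
            nrm = np.cross(e1, e2)
            u1 = e1 / np.linalg.norm(e1)
            u2 = np.cross(nrm, u1) / np.linalg.norm(np.cross(nrm, u1))
            P = np.array([[0, 0],
                          [e1 @ u1, 0],
                          [e2 @ u1, e2 @ u2]])
            area = 0.5 * abs(P[1, 0] * P[2, 1])
            # affine map P -> q; columns of J are the partial derivatives
            A = np.column_stack([P[1] - P[0], P[2] - P[0]])
            B = np.column_stack([q[1] - q[0], q[2] - q[0]])
            J = B @ np.linalg.inv(A)
            dzbar2 = 0.25 * ((J[0, 0] - J[1, 1]) ** 2 + (J[0, 1] + J[1, 0]) ** 2)
            total += area * dzbar2
        assert m.energy == pytest.approx(total, rel=1e-8)

    def test_sinusoidal_lamina_angle_distortion_below_5_degrees(self):
        n = 64
        xs = np.linspace(0, 100, n)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        h = 4.0 * np.sin(2 * np.pi * X / 100) * np.cos(2 * np.pi * Y / 100)
        m = flatten_lscm(_surface(h, (xs[1] - xs[0], xs[1] - xs[0])))

        def tri_angles(p):
            out = []
            for j in range(3):
                a = p[:, (j + 1) % 3] - p[:, j]
                b = p[:, (j + 2) % 3] - p[:, j]
                c = np.einsum("ij,ij->i", a, b) / (
                    np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
                out.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
            return np.stack(out, axis=1)

        a3 = tri_angles(m.vertices[m.triangles])
        uv3 = np.concatenate(
            [m.uv[m.triangles], np.zeros((len(m.triangles), 3, 1))], axis=2)
        a2 = tri_angles(uv3)
        assert np.abs(a3 - a2).max() < 5.0

        # no fold-overs: every planar triangle keeps positive area
        u3 = m.uv[m.triangles]
        signed = 0.5 * ((u3[:, 1, 0] - u3[:, 0, 0]) * (u3[:, 2, 1] - u3[:, 0, 1])
                        - (u3[:, 2, 0] - u3[:, 0, 0]) * (u3[:, 1, 1] - u3[:, 0, 1]))
        assert signed.min() > 0

    def test_disconnected_valid_region_rejected(self):
        h = _flat_heights((20, 20), 3.0)
        valid = np.zeros((20, 20), bool)
        valid[:8, :8] = True
        valid[12:, 12:] = True
        with pytest.raises(ValueError, match="disconnected"):
            flatten_lscm(Surface(h, valid, "On", (1.0, 1.0)))


def _flat_pair(shape=(40, 40), z_on=10.0, pitch=(1.0, 1.0)):
    on = Surface(_flat_heights(shape, z_on), np.ones(shape, bool), "On", pitch)
    off = Surface(_flat_heights(shape, z_on + 12.0), np.ones(shape, bool), "Off", pitch)
    return on, off


class TestRegisterInplane:
    def test_flat_surfaces_align_maps_at_center(self):
        on, off = _flat_pair()
        mo, mf = flatten_lscm(on), flatten_lscm(off)
        du, dv = register_inplane(mo, mf, on, off, window_um=16.0)
        c = np.array([[19.5, 19.5]])  # any shared point works for flat maps
        assert np.allclose(mo.uv_at(c), mf.with_offset((du, dv)).uv_at(c), atol=1e-6)

    def test_offset_application_is_idempotent(self):
        on, off = _flat_pair()
        mo, mf = flatten_lscm(on), flatten_lscm(off)
        du, dv = register_inplane(mo, mf, on, off, window_um=16.0)
        mf2 = mf.with_offset((du, dv))
        du2, dv2 = register_inplane(mo, mf2, on, off, window_um=16.0)
        assert abs(du2) < 1e-9 and abs(dv2) < 1e-9

    def test_flattest_pocket_is_chosen(self):
        # wavy surfaces with one deliberately flat 12-unit pocket: the
        # registration anchor must land on (or next to) the pocket
        shape = (48, 48)
        X, Y = np.meshgrid(np.arange(shape[0], dtype=float),
                           np.arange(shape[1], dtype=float), indexing="ij")
        wave = 3.0 * np.sin(X / 3.0) * np.cos(Y / 3.0)
        px, py = 30, 8  # pocket corner
        wave[px:px + 12, py:py + 12] = wave[px + 6, py + 6]
        on = Surface(10.0 + wave, np.ones(shape, bool), "On", (1.0, 1.0))
        off = Surface(22.0 + wave, np.ones(shape, bool), "Off", (1.0, 1.0))
        from arbordepth.laminar import _flattest_window_center

        cx, cy = _flattest_window_center(on, off, window_um=12.0)
        assert abs(cx - (px + 5.5)) <= 6.0 and abs(cy - (py + 5.5)) <= 6.0

    def test_window_larger_than_grid_rejected(self):
        on, off = _flat_pair(shape=(10, 10))
        mo, mf = flatten_lscm(on), flatten_lscm(off)
        with pytest.raises(ValueError, match="window"):
            register_inplane(mo, mf, on, off, window_um=50.0)


class TestBuildWarp:
    def test_identity_case_flat_parallel_surfaces(self):
        on, off = _flat_pair(shape=(40, 40), z_on=10.0)
        grid = VoxelGrid((40, 40, 35), (1.0, 1.0, 1.0))
        mo, mf = flatten_lscm(on), flatten_lscm(off)
        du, dv = register_inplane(mo, mf, on, off, window_um=16.0)
        warp = build_warp(mo, mf.with_offset((du, dv)), on, off, grid)

        idx = np.array([[20, 20, 10], [20, 20, 16], [20, 20, 22],
                        [8, 30, 10], [30, 8, 22]])
        u, v, depth, w = warp.transform(idx)
        # On surface (z=10) -> depth 0; midway (z=16) -> 6; Off (z=22) -> 12
        assert np.allclose(depth[[0, 3]], 0.0, atol=1e-9)
        assert depth[1] == pytest.approx(6.0)
        assert np.allclose(depth[[2, 4]], 12.0, atol=1e-9)
        # volume-compensation weights are unity for an isometry
        assert np.allclose(w, 1.0, atol=1e-6)
        # (u, v) is a rigid motion of (x, y): pairwise distances preserved
        xy = idx[:, :2].astype(float)
        for i in range(len(idx)):
            for j in range(i):
                dxy = np.linalg.norm(xy[i] - xy[j])
                duv = np.hypot(u[i] - u[j], v[i] - v[j])
                assert duv == pytest.approx(dxy, abs=1e-5)

    def test_depth_strictly_increases_along_every_column(self):
        on, off = _flat_pair(shape=(30, 30), z_on=8.0)
        grid = VoxelGrid((30, 30, 32), (1.0, 1.0, 1.0))
        mo, mf = flatten_lscm(on), flatten_lscm(off)
        warp = build_warp(mo, mf, on, off, grid)
        col = np.array([[12, 17, z] for z in range(32)])
        _, _, depth, _ = warp.transform(col)
        assert np.all(np.diff(depth) > 0)
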
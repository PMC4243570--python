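"""Shared fixtures and independent mini-oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from arbordepth.volio import Skeleton, SkeletonNode, VoxelGrid


def _seg_dist(a0, a1, b0, b1):
    """Minimum distance between 3-D segments a0-a1 and b0-b1."""
    ts = np.linspace(0.0, 1.0, 24)
    pa = a0[None, :] + ts[:, None] * (a1 - a0)[None, :]
    pb = b0[None, :] + ts[:, None] * (b1 - b0)[None, :]
    return np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2).min()


def random_tree_skeleton(rng, n_nodes=30, box_um=16.0, clearance_um=1.5, z_frac=0.5):
    """Random tree whose non-adjacent branches keep a geometric clearance,
    so the digital rendering stays homotopy-equivalent to a tree.

    Each new node attaches to the nearest existing node; a candidate edge
    is rejected when it comes within ``clearance_um`` of any edge it does
    not share an endpoint with (digital lines wander < half a voxel, so
    clearance above one voxel pitch keeps branches from touching).
    """
    pts = [rng.uniform(0.35 * box_um, 0.65 * box_um, size=3)]
    edges_geo = []  # (i, j, p_i, p_j) with node list indices
    tries = 0
    while len(pts) < n_nodes and tries < 4000:
        tries += 1
        cand = rng.uniform(1.0, box_um - 1.0, size=3)
        cand[2] = rng.uniform(1.0, max(z_frac * box_um, 2.0))
        d = [np.linalg.norm(cand - p) for p in pts]
        parent = int(np.argmin(d))
        if d[parent] < 1.5 * clearance_um:
            continue
        ok = True
        pp = np.asarray(pts[parent])
        for (i, j, pi, pj) in edges_geo:
            if parent in (i, j):
                # shared endpoint: beyond a short corner zone the two edges
                # must still keep clear, or the V digitizes into a loop
                shared = pi if parent == i else pj
                far = pj if parent == i else pi
                t_new = min(0.45, 1.2 / (np.linalg.norm(cand - pp) + 1e-9))
                t_old = min(0.45, 1.2 / (np.linalg.norm(far - shared) + 1e-9))
                a = pp + t_new * (cand - pp)
                b = shared + t_old * (far - shared)
                if _seg_dist(a, cand, b, far) < clearance_um:
                    ok = False
                    break
                continue
            if _seg_dist(pp, cand, pi, pj) < clearance_um:
                ok = False
                break
        if ok and min(
            (np.linalg.norm(cand - p) for k, p in enumerate(pts) if k != parent),
            default=np.inf,
        ) >= clearance_um:
            edges_geo.append((parent, len(pts), np.asarray(pts[parent]), cand))
            pts.append(cand)
    nodes = [SkeletonNode(1, 1, *pts[0], 1.0, -1)]
    for (parent, child, _, _) in edges_geo:
        nodes.append(SkeletonNode(child + 1, 3, *pts[child], 1.0, parent + 1))
    return Skeleton(nodes)


def brute_force_simple(patch: np.ndarray) -> bool:
    """Global-topology oracle: embed the 3x3x3 patch in a padded volume and
    compare component/cavity/Euler counts before vs after flipping the
    center (independent of the local topological-number characterization).
    """
    from arbordepth.topology3d import topology_summary

    vol = np.zeros((5, 5, 5), dtype=bool)
    vol[1:4, 1:4, 1:4] = patch
    with_center = vol.copy()
    with_center[2, 2, 2] = True
    without_center = vol.copy()
    without_center[2, 2, 2] = False
    return (
        topology_summary(with_center).as_tuple()
        == topology_summary(without_center).as_tuple()
    )


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid((16, 16, 16), (0.4, 0.4, 0.5))


@pytest.fixture(scope="session")
def w3_phantom():
    """One standard W3 phantom, shared by the slower integration tests."""
    from arbordepth.synthdata import PhantomSpec, make_phantom

    return make_phantom(PhantomSpec(cell_type="W3", seed=0))
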
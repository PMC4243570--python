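"""Convolutional enhancement network: architecture, inference, thresholding.

The network transforms noisy grayscale stacks of sparsely labeled neurons
into per-voxel neurite probabilities.  Architecture: a stack of 3-D
convolutional layers with all-to-all feature connectivity and sigmoid
nonlinearities; the final fully connected hidden layer is realized as a
1x1x1 convolution (its dense equivalent), so inference stays convolutional
and dense-per-voxel.  Training is out of scope here: weights are loaded
from an ``.npz`` container, and the pipeline defaults to the 60%-of-max
threshold baseline when none is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import BinaryVolume, ImageStack

__all__ = [
    "NetworkSpec",
    "default_network_spec",
    "receptive_field",
    "receptive_field_um",
    "random_weights",
    "save_weights",
    "load_weights",
    "forward",
    "threshold_binarize",
]


class SpecError(ValueError):
    """Network specification / weight mismatch."""


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered (filter-size triple, feature-map count) per layer.

    Filter sizes must be odd in every dimension so each layer is centered.
    """

    layers: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.layers) < 1:
            raise SpecError("network needs at least one layer")
        for fs, nf in self.layers:
            if len(fs) != 3 or any(int(k) % 2 == 0 or int(k) < 1 for k in fs):
                raise SpecError(f"filter size {fs} must be odd in every dimension")
            if nf < 1:
                raise SpecError("feature count must be >= 1")


def default_network_spec() -> NetworkSpec:
    """The 8-hidden-layer enhancement architecture.

    Eight perceptrons per hidden layer except the last hidden layer, which
    is fully connected with 100 units (here a 1x1x1 convolution), followed
    by a single-feature 1x1x1 output layer.
    """
    sizes = [(5, 5, 1), (5, 5, 1), (3, 3, 3), (5, 5, 1),
             (3, 3, 3), (3, 3, 3), (1, 1, 1), (1, 1, 1)]
    feats = [8, 8, 8, 8, 8, 8, 8, 100]
    layers = list(zip(sizes, feats)) + [((1, 1, 1), 1)]
    return NetworkSpec(tuple(layers))


def receptive_field(spec: NetworkSpec) -> tuple[int, int, int]:
    """Voxel extent of the input patch influencing one output voxel.

    Per axis: ``1 + sum over layers of (filter size - 1)``.
    """
    ext = np.ones(3, dtype=int)
    for fs, _ in spec.layers:
        ext += np.asarray(fs, dtype=int) - 1
    return tuple(int(e) for e in ext)


def receptive_field_um(spec: NetworkSpec, pitch=(0.4, 0.4, 0.5)) -> tuple[float, float, float]:
    return tuple(float(e * p) for e, p in zip(receptive_field(spec), pitch))


# ---------------------------------------------------------------------------
# Weights


def random_weights(spec: NetworkSpec, seed: int = 0, scale: float = 0.5) -> dict:
    """Gaussian random weights dimensionally consistent with the spec."""
    rng = np.random.default_rng(seed)
    weights = {}
    n_in = 1
    for li, (fs, nf) in enumerate(spec.layers):
        weights[f"w{li}"] = rng.normal(0.0, scale, size=(nf, n_in, *fs))
        weights[f"b{li}"] = rng.normal(0.0, scale, size=nf)
        n_in = nf
    return weights


def save_weights(path, weights: dict) -> None:
    np.savez(path, **weights)


def load_weights(path) -> dict:
    with np.load(path) as npz:
        return {k: npz[k] for k in npz.files}


def _check_weights(spec: NetworkSpec, weights: dict) -> None:
    n_in = 1
    for li, (fs, nf) in enumerate(spec.layers):
        w = weights.get(f"w{li}")
        b = weights.get(f"b{li}")
        if w is None or b is None:
            raise SpecError(f"missing weights for layer {li}")
        if tuple(w.shape) != (nf, n_in, *fs) or tuple(b.shape) != (nf,):
            raise SpecError(
                f"layer {li}: weight shape {w.shape} inconsistent with spec ({nf}, {n_in}, {fs})"
            )
        n_in = nf
    if n_in != 1:
        raise SpecError("final layer must output a single feature map")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def forward(spec: NetworkSpec, weights: dict, stack: ImageStack) -> ImageStack:
    """Dense per-voxel inference; mirror padding keeps output shape == input.

    Every layer applies its convolutions with all-to-all feature
    connectivity, adds the bias and passes through a sigmoid, so outputs
    are probabilities in (0, 1).
    """
    _check_weights(spec, weights)
    feats = [np.asarray(stack.values, dtype=float)]
    for li, (fs, nf) in enumerate(spec.layers):
        w, b = weights[f"w{li}"], weights[f"b{li}"]
        out = []
        for o in range(nf):
            acc = np.full(feats[0].shape, float(b[o]))
            for i, f in enumerate(feats):
                kern = w[o, i]
                if kern.shape == (1, 1, 1):
                    acc += f * kern[0, 0, 0]
                else:
                    acc += ndimage.correlate(f, kern, mode="mirror")
            out.append(_sigmoid(acc))
        feats = out
    return ImageStack(stack.grid, feats[0], role=stack.role)


# ---------------------------------------------------------------------------
# Threshold baseline


def threshold_binarize(stack: ImageStack, frac: float = 0.6) -> BinaryVolume:
    """Binarize at ``frac`` times the global intensity maximum."""
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    vmax = float(stack.values.max())
    if vmax <= 0:
        raise ValueError("cannot threshold an all-zero stack")
    return BinaryVolume(stack.grid, stack.values >= frac * vmax)
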
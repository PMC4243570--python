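"""End-to-end orchestration: stacks in, depth profile and statistics out.

Chains enhancement (threshold baseline or network inference),
post-processing, fiducial-surface detection and flattening, in-plane
registration, warp-field construction, Kaiser-Bessel depth gridding and
peak detection.  Used by the command-line front-end and directly from
Python.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np

from . import enhance, laminar, postprocess, profiles_stats
from .volio import BinaryVolume, ImageStack, log, stage_timer

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of the pipeline, with its standard default."""

    threshold_frac: float = 0.6        # enhancement threshold, fraction of max
    rounds: int = 62                   # inflation rounds (trace path)
    enhance_mode: str = "threshold"    # "threshold" | "network"
    weights_path: str | None = None    # network weights (.npz), network mode
    dilation_radius: int = 2
    size_threshold: int = 500
    search_radius: int = 10
    postprocess_threshold: float = 0.7
    conservative_threshold: float = 0.5
    kernel: str = "ball"
    smooth_sigma: float = 1.0
    flatness_window_um: float = 32.0
    fit_radius_um: float = 25.0
    bin_width_um: float = 0.5
    second_peak_exclusion_um: float = 6.0
    truncate_below_um: float = -6.0    # applied on the threshold path
    bistratified: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def as_dict(self) -> dict:
        return asdict(self)


def run_pipeline(
    neuron: ImageStack,
    chat: ImageStack,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the automated depth-profile pipeline on a two-channel stack.

    Returns a dict with the cleaned mask, detected surfaces, conformal
    maps, warp field, raw and normalized depth profiles, and the peak
    report.
    """
    cfg = config or PipelineConfig()

    with stage_timer("enhance"):
        if cfg.enhance_mode == "network":
            if not cfg.weights_path:
                raise ValueError("network mode needs weights_path")
            spec = enhance.default_network_spec()
            prob = enhance.forward(spec, enhance.load_weights(cfg.weights_path), neuron)
        elif cfg.enhance_mode == "threshold":
            binary = enhance.threshold_binarize(neuron, cfg.threshold_frac)
            prob = ImageStack(neuron.grid, binary.mask.astype(np.float32), role="neuron")
        else:
            raise ValueError(f"unknown enhance mode {cfg.enhance_mode!r}")

    with stage_timer("postprocess"):
        params = postprocess.PostprocessParams(
            dilation_radius=cfg.dilation_radius,
            size_threshold=cfg.size_threshold,
            search_radius=cfg.search_radius,
            threshold=cfg.postprocess_threshold,
            conservative_threshold=cfg.conservative_threshold,
            kernel=cfg.kernel,
        )
        mask = postprocess.postprocess(prob, params)

    with stage_timer("surfaces"):
        on, off = laminar.detect_surfaces(chat, smooth_sigma=cfg.smooth_sigma)

    with stage_timer("flatten"):
        on_map = laminar.flatten_lscm(on)
        off_map = laminar.flatten_lscm(off)
        du, dv = laminar.register_inplane(on_map, off_map, on, off,
                                          window_um=cfg.flatness_window_um)
        off_map = off_map.with_offset((du, dv))

    with stage_timer("warp"):
        warp = laminar.build_warp(on_map, off_map, on, off, neuron.grid,
                                  fit_radius_um=cfg.fit_radius_um)
        idx, (u, v, depth, weight) = warp.points_for_mask(mask)

    with stage_timer("profile"):
        profile = profiles_stats.depth_profile(depth, weight)
        peak_src = profile
        if cfg.enhance_mode == "threshold":
            peak_src = profiles_stats.truncate_profile(profile, cfg.truncate_below_um)
        peaks = profiles_stats.find_peaks(peak_src, bistratified=cfg.bistratified)

    log.info("pipeline: %d voxels retained, peak at %.2f μm", mask.count(), peaks.peak1)
    return {
        "mask": mask,
        "surfaces": (on, off),
        "maps": (on_map, off_map),
        "offset": (du, dv),
        "warp": warp,
        "voxels": idx,
        "depths": depth,
        "weights": weight,
        "profile": profile,
        "profile_normalized": profile.normalize(),
        "peaks": peaks,
    }
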
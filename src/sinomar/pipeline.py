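"""End-to-end orchestration of the six reconstruction strategies.

The proposed chain for a sparse-view, metal-bearing scan is::

    initial FBP -> segment metal -> locate metal trace -> up-sample views
    -> remove metal trace -> linear interpolation -> sinogram network
    -> FBP -> image network -> reinsert metal

The five comparison baselines reuse exactly the same stages with one piece
swapped out: plain FBP / PWLS of the sparse sinogram, FBP of the
linear-interpolated sinogram, linear interpolation + image network only, and
sinogram network + FBP only.  Metal removal/reinsertion is applied uniformly
across methods (configurable off, to reproduce naive reconstructions with
full metal artifacts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .completion import (
    guarded_synthesize,
    linear_interpolate,
    tile_apply,
    upsample_view_grid,
)
from .geometry import ImageSlice, Sinogram
from .metal import MetalMask, compute_metal_trace, reinsert_metal, segment_metal
from .metal import remove_metal as _remove_metal
from .metrics import ROI, MetricReport, cnr, psnr, rmse, ssim
from .recon import FBPConfig, IRConfig, fbp_reconstruct, pwls_reconstruct
from .simulate import FIBROGLANDULAR_MU, METAL_MU, default_metal_threshold

__all__ = [
    "PipelineConfig",
    "run_proposed",
    "run_baseline",
    "compare_methods",
    "BASELINE_METHODS",
]

BASELINE_METHODS = (
    "fbp",
    "ir",
    "lininterp",
    "image_denoise_only",
    "sino_unet_only",
    "proposed",
)


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    decimation_factor: int = 4
    metal_threshold: float = default_metal_threshold(FIBROGLANDULAR_MU, METAL_MU)
    metal_handling: bool = True
    trace_dilate_bins: int = 1
    guard_synthesis: bool = True
    guard_margin: float = 0.02
    fbp: FBPConfig = field(default_factory=FBPConfig)
    ir: IRConfig = field(default_factory=lambda: IRConfig(n_iterations=20))
    sino_model: object | None = None
    image_model: object | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "decimation_factor": self.decimation_factor,
            "metal_threshold": self.metal_threshold,
            "metal_handling": self.metal_handling,
            "trace_dilate_bins": self.trace_dilate_bins,
            "guard_synthesis": self.guard_synthesis,
            "guard_margin": self.guard_margin,
            "fbp": {"filter_name": self.fbp.filter_name, "cutoff": self.fbp.cutoff},
            "ir": {
                "smoothness": self.ir.smoothness,
                "edge_preservation": self.ir.edge_preservation,
                "n_iterations": self.ir.n_iterations,
            },
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = {}
        for key in ("decimation_factor", "metal_threshold", "metal_handling",
                    "trace_dilate_bins", "guard_synthesis", "guard_margin", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "fbp" in raw:
            kwargs["fbp"] = FBPConfig(**raw["fbp"])
        if "ir" in raw:
            kwargs["ir"] = IRConfig(**raw["ir"])
        return cls(**kwargs)


class MissingModelError(RuntimeError):
    pass


def _require_model(config: PipelineConfig, which: str):
    model = getattr(config, which)
    if model is None:
        raise MissingModelError(
            f"pipeline stage requires config.{which} (trained network weights)"
        )
    return model


def _segment_from_initial_fbp(sparse: Sinogram, config: PipelineConfig) -> MetalMask:
    """Metal mask thresholded on the initial FBP of the input sinogram."""
    initial = fbp_reconstruct(sparse, config.fbp)
    return segment_metal(initial, config.metal_threshold)


def _denoise_image(image: ImageSlice, model) -> ImageSlice:
    values = tile_apply(model, image.values, model.patch_size)
    return ImageSlice(values, image.geometry)


def run_proposed(
    sparse_sino: Sinogram,
    config: PipelineConfig,
    return_intermediates: bool = False,
):
    """Full two-network pipeline on a sparse-view (optionally metal-bearing)
    sinogram.  Deterministic given fixed model weights."""
    sino_model = _require_model(config, "sino_model")
    image_model = _require_model(config, "image_model")
    inter: dict = {}

    mask = (
        _segment_from_initial_fbp(sparse_sino, config)
        if config.metal_handling
        else MetalMask(np.zeros((sparse_sino.geometry.image_size,) * 2, bool), np.empty(0))
    )
    inter["metal_mask"] = mask
    up = upsample_view_grid(sparse_sino, config.decimation_factor)
    trace_support = None
    if config.metal_handling and not mask.is_empty:
        trace = compute_metal_trace(mask, up.geometry, dilate_bins=config.trace_dilate_bins)
        up = _remove_metal(up, trace)
        inter["metal_trace"] = trace
        trace_support = trace.support
    invalid = ~up.valid_mask
    lin = linear_interpolate(up)
    inter["lininterp_sinogram"] = lin
    if config.guard_synthesis:
        syn, used = guarded_synthesize(
            lin, sino_model, invalid_mask=invalid, trace_mask=trace_support,
            margin=config.guard_margin, fbp_config=config.fbp,
        )
        inter["synthesis_accepted"] = used
    else:
        from .completion import unet_synthesize

        syn = unet_synthesize(lin, sino_model, invalid_mask=invalid, trace_mask=trace_support)
    inter["synthesized_sinogram"] = syn
    recon = fbp_reconstruct(syn, config.fbp)
    inter["fbp_image"] = recon
    denoised = _denoise_image(recon, image_model)
    final = reinsert_metal(denoised, mask)
    if return_intermediates:
        return final, inter
    return final


def _completed_sparse(sparse: Sinogram, config: PipelineConfig, mask: MetalMask) -> Sinogram:
    """Metal removal + detector-direction gap filling at the sparse geometry
    (for the methods that reconstruct from the sparse sinogram directly)."""
    if config.metal_handling and not mask.is_empty:
        trace = compute_metal_trace(
            mask, sparse.geometry, dilate_bins=config.trace_dilate_bins
        )
        return linear_interpolate(_remove_metal(sparse, trace))
    return sparse


def run_baseline(sparse_sino: Sinogram, method: str, config: PipelineConfig) -> ImageSlice:
    """One of the six comparison strategies (``proposed`` included)."""
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {BASELINE_METHODS}")
    if method == "proposed":
        return run_proposed(sparse_sino, config)

    mask = (
        _segment_from_initial_fbp(sparse_sino, config)
        if config.metal_handling
        else MetalMask(np.zeros((sparse_sino.geometry.image_size,) * 2, bool), np.empty(0))
    )

    if method == "fbp":
        img = fbp_reconstruct(_completed_sparse(sparse_sino, config, mask), config.fbp)
        return reinsert_metal(img, mask)
    if method == "ir":
        img = pwls_reconstruct(_completed_sparse(sparse_sino, config, mask), config.ir)
        return reinsert_metal(img, mask)

    # methods operating on the up-sampled view grid
    up = upsample_view_grid(sparse_sino, config.decimation_factor)
    trace_support = None
    if config.metal_handling and not mask.is_empty:
        trace = compute_metal_trace(mask, up.geometry, dilate_bins=config.trace_dilate_bins)
        up = _remove_metal(up, trace)
        trace_support = trace.support
    invalid = ~up.valid_mask
    lin = linear_interpolate(up)

    if method == "lininterp":
        return reinsert_metal(fbp_reconstruct(lin, config.fbp), mask)
    if method == "image_denoise_only":
        model = _require_model(config, "image_model")
        img = _denoise_image(fbp_reconstruct(lin, config.fbp), model)
        return reinsert_metal(img, mask)
    # sino_unet_only
    sino_model = _require_model(config, "sino_model")
    if config.guard_synthesis:
        syn, _ = guarded_synthesize(
            lin, sino_model, invalid_mask=invalid, trace_mask=trace_support,
            margin=config.guard_margin, fbp_config=config.fbp,
        )
    else:
        from .completion import unet_synthesize

        syn = unet_synthesize(lin, sino_model, invalid_mask=invalid, trace_mask=trace_support)
    return reinsert_metal(fbp_reconstruct(syn, config.fbp), mask)


def compare_methods(
    sparse_sino: Sinogram,
    reference: ImageSlice,
    config: PipelineConfig,
    methods: tuple[str, ...] = BASELINE_METHODS,
    roi_target: ROI | None = None,
    roi_reference: ROI | None = None,
    evaluation_mask: np.ndarray | None = None,
) -> list[MetricReport]:
    """Run each method and score it against the reference image.

    ``evaluation_mask`` restricts RMSE/SSIM to artifact-free evaluation
    pixels (e.g. excluding the metal support); CNR needs the two tissue ROIs.
    """
    reports = []
    roi_eval = ROI(mask=evaluation_mask) if evaluation_mask is not None else None
    for method in methods:
        img = run_baseline(sparse_sino, method, config)
        report = MetricReport(
            method=method,
            ssim=ssim(img.values, reference.values, roi=roi_eval),
            psnr=psnr(img.values, reference.values),
            rmse=rmse(img.values, reference.values, roi=roi_eval),
        )
        if roi_target is not None and roi_reference is not None:
            report.cnr = cnr(img.values, roi_target, roi_reference)
        reports.append(report)
    return reports
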
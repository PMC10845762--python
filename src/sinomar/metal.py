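"""Metal workflow: image-domain segmentation, sinogram-domain trace location,
track removal and final reinsertion.

A metal object (e.g. a localization-needle marker) corrupts every line
integral whose ray intersects it.  The workflow segments the metal in the
image domain by thresholding, forward-projects the metal-only image to locate
the corrupted "metal trace" in the sinogram, flags those bins invalid so the
completion stage re-synthesizes them, and finally writes the segmented metal
values back into the denoised image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .geometry import GeometryError, ImageSlice, ScanGeometry, Sinogram, forward_project

__all__ = [
    "MetalMask",
    "MetalTrace",
    "segment_metal",
    "compute_metal_trace",
    "remove_metal",
    "reinsert_metal",
]


@dataclass
class MetalMask:
    """Boolean metal support on the image grid plus the attenuation values at
    the supported pixels."""

    support: np.ndarray
    metal_values: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool)
        self.metal_values = np.asarray(self.metal_values, dtype=np.float64)
        if self.metal_values.shape != (int(self.support.sum()),):
            raise ValueError("metal_values must hold exactly one value per supported pixel")

    @property
    def is_empty(self) -> bool:
        return not self.support.any()

    def as_image(self, geometry: ScanGeometry) -> ImageSlice:
        """Metal-only image: metal values on support, zero elsewhere."""
        out = np.zeros(self.support.shape, dtype=np.float64)
        out[self.support] = self.metal_values
        return ImageSlice(out, geometry)


@dataclass
class MetalTrace:
    """Boolean support of the metal trace on the sinogram grid (bin, view)."""

    support: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool)

    @property
    def is_empty(self) -> bool:
        return not self.support.any()


def segment_metal(image: ImageSlice, threshold: float) -> MetalMask:
    """Threshold segmentation of metal: support = pixels with value >= threshold.

    The comparison is inclusive: a pixel exactly at the threshold belongs to
    the metal.  An empty mask is a valid outcome.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    support = image.values >= threshold
    return MetalMask(support, image.values[support])


def compute_metal_trace(
    mask: MetalMask,
    geometry: ScanGeometry,
    trace_threshold: float = 0.0,
    dilate_bins: int = 1,
) -> MetalTrace:
    """Locate the metal trace by forward-projecting the metal-only image.

    Trace support = sinogram bins whose metal-only line integral exceeds
    ``trace_threshold`` (default 0 plus a numerical epsilon).  ``dilate_bins``
    dilates the trace along the detector axis (default 1 bin) to absorb
    partial-volume bins at the trace edge, since threshold-based metal
    extraction is never pixel-exact on measured data.
    """
    if mask.support.shape != (geometry.image_size, geometry.image_size):
        raise GeometryError("metal mask grid does not match geometry")
    if mask.is_empty:
        return MetalTrace(np.zeros((geometry.n_bins, geometry.n_views), dtype=bool))
    metal_sino = forward_project(mask.as_image(geometry), geometry)
    eps = 1e-9 * max(1.0, float(np.abs(metal_sino.values).max()))
    support = metal_sino.values > trace_threshold + eps
    if dilate_bins > 0:
        structure = np.ones((2 * dilate_bins + 1, 1), dtype=bool)  # detector axis only
        support = binary_dilation(support, structure=structure)
    return MetalTrace(support)


def remove_metal(sinogram: Sinogram, trace: MetalTrace) -> Sinogram:
    """Flag the metal-trace bins invalid.  Values are left in place but the
    validity mask marks them as undefined for all downstream consumers."""
    if trace.support.shape != sinogram.values.shape:
        raise GeometryError("trace shape does not match sinogram")
    out = sinogram.copy()
    out.valid_mask &= ~trace.support
    return out


def reinsert_metal(denoised: ImageSlice, mask: MetalMask) -> ImageSlice:
    """Write the segmented metal values back at their original positions."""
    if mask.support.shape != denoised.values.shape:
        raise GeometryError("metal mask grid does not match image")
    out = denoised.copy()
    out.values[mask.support] = mask.metal_values
    return out
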
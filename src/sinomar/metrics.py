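"""Image-quality metrics: RMSE, PSNR, global SSIM and CNR, plus line profiles.

These are the four figures of merit the pipeline is compared with:

* ``rmse``  — root-mean-square error over an ROI (or the whole array),
  sqrt(sum((test - ref)^2) / N).
* ``psnr``  — 10 log10(m_peak^2 / MSE) with m_peak the maximum intensity over
  *both* arrays (not a fixed bit-depth range).
* ``ssim``  — the *global* (single-window) structural similarity computed
  from the means, variances and covariance of the two arrays.  In the
  default ``literal`` mode the stabilizers k1 = 0.001 and k2 = 0.03 are added
  directly inside the formula; ``scaled`` mode uses the conventional
  c_i = (k_i L)^2 with L the reference dynamic range.  A sliding-window SSIM
  is deliberately not the default.
* ``cnr``   — (mean_target - mean_reference) / sqrt(sd_target^2 + sd_ref^2),
  sign preserved; e.g. between fibroglandular and adipose ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["ROI", "MetricReport", "rmse", "psnr", "ssim", "cnr", "line_profile"]


@dataclass(frozen=True)
class ROI:
    """Rectangular or mask-defined pixel set with a role tag.

    Rectangular form: ``ROI(row, col, height, width)`` (top-left inclusive).
    Mask form: ``ROI(mask=<bool array>)``.
    """

    row: int = 0
    col: int = 0
    height: int = 0
    width: int = 0
    mask: np.ndarray | None = None
    role: str = "target"

    def indices(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, bool)
            if m.shape != shape:
                raise ValueError("ROI mask shape does not match array")
        else:
            if self.height <= 0 or self.width <= 0:
                raise ValueError("ROI is empty")
            if (
                self.row < 0
                or self.col < 0
                or self.row + self.height > shape[0]
                or self.col + self.width > shape[1]
            ):
                raise ValueError("ROI lies outside the array")
            m = np.zeros(shape, bool)
            m[self.row : self.row + self.height, self.col : self.col + self.width] = True
        if not m.any():
            raise ValueError("ROI is empty")
        return m

    def extract(self, array: np.ndarray) -> np.ndarray:
        return np.asarray(array)[self.indices(np.asarray(array).shape)]


@dataclass
class MetricReport:
    """One row of a method-comparison table."""

    method: str
    ssim: float = np.nan
    cnr: float = np.nan
    psnr: float = np.nan
    rmse: float = np.nan
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "ssim": self.ssim,
            "cnr": self.cnr,
            "psnr": self.psnr,
            "rmse": self.rmse,
        }


def _pair(test, reference):
    test = np.asarray(test, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {reference.shape}")
    return test, reference


def rmse(test: np.ndarray, reference: np.ndarray, roi: ROI | None = None) -> float:
    test, reference = _pair(test, reference)
    if roi is not None:
        test, reference = roi.extract(test), roi.extract(reference)
    return float(np.sqrt(np.mean((test - reference) ** 2)))


def psnr(test: np.ndarray, reference: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the arrays are identical."""
    test, reference = _pair(test, reference)
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0.0:
        return float("inf")
    m_peak = float(max(test.max(), reference.max()))
    return float(10.0 * np.log10(m_peak**2 / mse))


def ssim(
    test: np.ndarray,
    reference: np.ndarray,
    k1: float = 0.001,
    k2: float = 0.03,
    roi: ROI | None = None,
    stabilizer_mode: str = "literal",
) -> float:
    """Global single-window SSIM.

    ``stabilizer_mode='literal'`` (default) adds k1, k2 directly:
    ((2 m_r m_t + k1)(2 cov + k2)) / ((m_r^2 + m_t^2 + k1)(var_r + var_t + k2)).
    ``'scaled'`` uses c_i = (k_i L)^2 with L = reference dynamic range.
    Symmetric in its two arguments; 1.0 for identical inputs.
    """
    test, reference = _pair(test, reference)
    if roi is not None:
        test, reference = roi.extract(test), roi.extract(reference)
    if stabilizer_mode == "literal":
        c1, c2 = k1, k2
    elif stabilizer_mode == "scaled":
        L = float(reference.max() - reference.min())
        if L == 0:
            L = 1.0
        c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    else:
        raise ValueError("stabilizer_mode must be 'literal' or 'scaled'")
    m_t, m_r = test.mean(), reference.mean()
    var_t, var_r = test.var(), reference.var()
    cov = ((test - m_t) * (reference - m_r)).mean()
    num = (2 * m_r * m_t + c1) * (2 * cov + c2)
    den = (m_r**2 + m_t**2 + c1) * (var_r + var_t + c2)
    return float(num / den)


def cnr(image: np.ndarray, roi_target: ROI, roi_reference: ROI) -> float:
    """Contrast-to-noise ratio between two disjoint ROIs; sign preserved."""
    image = np.asarray(image, dtype=np.float64)
    m_t_idx = roi_target.indices(image.shape)
    m_r_idx = roi_reference.indices(image.shape)
    if (m_t_idx & m_r_idx).any():
        raise ValueError("target and reference ROIs must be disjoint")
    tgt, ref = image[m_t_idx], image[m_r_idx]
    denom = float(np.sqrt(tgt.std() ** 2 + ref.std() ** 2))
    contrast = float(tgt.mean() - ref.mean())
    if denom == 0.0:
        if contrast == 0.0:
            warnings.warn("both ROIs are constant and equal; CNR defined as 0")
            return 0.0
        return float(np.inf) * np.sign(contrast)
    return contrast / denom


def line_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    n_samples: int = 100,
) -> np.ndarray:
    """Bilinear samples along a segment, as an ``(n_samples, 2)`` array of
    (position along the segment, value).  ``start``/``end`` are (row, col)
    pixel coordinates and must lie inside the grid."""
    image = np.asarray(image, dtype=np.float64)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    for p in (start, end):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValueError(f"profile endpoint {p} outside the image grid")
    frac = np.linspace(0.0, 1.0, n_samples)
    rows = start[0] + frac * (end[0] - start[0])
    cols = start[1] + frac * (end[1] - start[1])
    values = map_coordinates(image, [rows, cols], order=1)
    length = np.hypot(end[0] - start[0], end[1] - start[1])
    return np.column_stack([frac * length, values])
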
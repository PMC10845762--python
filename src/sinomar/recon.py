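"""Filtered backprojection and a penalized weighted-least-squares baseline.

FBP is the pipeline's reconstructor (default: Shepp-Logan filter, relative
cutoff 1.0).  PWLS with a Huber edge-preserving roughness penalty serves only
as the iterative-reconstruction comparison baseline; its two scalar knobs are
the smoothness weight beta and the edge-preservation threshold delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import ImageSlice, Sinogram, back_project_adjoint, forward_project

__all__ = [
    "FBPConfig",
    "IRConfig",
    "build_filter",
    "fbp_reconstruct",
    "pwls_reconstruct",
    "reprojection_consistency",
]

log = logging.getLogger(__name__)

_FILTERS = ("ram-lak", "shepp-logan")

# Comparison-baseline preset: penalized reconstruction with smoothness 150,
# edge preservation 1e-5, 100 iterations.
PAPER_IR_PRESET = dict(smoothness=150.0, edge_preservation=1e-5, n_iterations=100)


@dataclass(frozen=True)
class FBPConfig:
    """Filter choice for FBP.  Default mirrors the reference setting:
    Shepp-Logan filter at relative cutoff 1.0."""

    filter_name: str = "shepp-logan"
    cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.filter_name not in _FILTERS:
            raise ValueError(f"filter_name must be one of {_FILTERS}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in (0, 1]")


@dataclass(frozen=True)
class IRConfig:
    """Knobs of the PWLS baseline: beta (smoothness), delta (edge
    preservation) and the iteration count."""

    smoothness: float = 150.0
    edge_preservation: float = 1e-5
    n_iterations: int = 100

    def __post_init__(self) -> None:
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        if self.edge_preservation <= 0:
            raise ValueError("edge_preservation must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def build_filter(filter_name: str, cutoff: float, n_bins: int, bin_spacing: float = 1.0) -> np.ndarray:
    """Frequency response of the reconstruction filter, for an FFT of length
    ``n_bins`` with sample spacing ``bin_spacing``.

    The response is real and non-negative, zero at DC, and zero above
    ``cutoff`` times the Nyquist frequency.  ``ram-lak`` is the plain ramp
    |f|; ``shepp-logan`` multiplies the ramp by a sinc window
    ``sinc(f / (2 f_N))`` (normalized sinc), trading resolution for noise.
    """
    if filter_name not in _FILTERS:
        raise ValueError(f"filter_name must be one of {_FILTERS}")
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    freqs = np.fft.fftfreq(n_bins, d=bin_spacing)
    nyquist = 0.5 / bin_spacing
    response = np.abs(freqs)
    if filter_name == "shepp-logan":
        response = response * np.sinc(freqs / (2.0 * nyquist))
    response[np.abs(freqs) > cutoff * nyquist + 1e-12] = 0.0
    return response


class InvalidSinogramError(ValueError):
    """Raised when a reconstructor receives a sinogram with missing entries."""


def _filtered_projections(sino: Sinogram, config: FBPConfig) -> np.ndarray:
    g = sino.geometry
    # Zero-pad to >= 4x the detector length so the discrete ramp resolves the
    # low frequencies well enough for quantitative interior values.
    n_pad = int(2 ** np.ceil(np.log2(4 * g.n_bins)))
    response = build_filter(config.filter_name, config.cutoff, n_pad, g.bin_spacing)
    spectrum = np.fft.fft(sino.values, n=n_pad, axis=0)
    filtered = np.real(np.fft.ifft(spectrum * response[:, None], axis=0))
    return filtered[: g.n_bins]


def fbp_reconstruct(sinogram: Sinogram, config: FBPConfig | None = None) -> ImageSlice:
    """Filtered backprojection onto the geometry's image grid.

    The sinogram must be fully valid (complete missing data upstream).
    Backprojection interpolates linearly in the detector coordinate; the
    angular integral over the full 360-degree scan is averaged over the two
    conjugate half-scans.
    """
    if config is None:
        config = FBPConfig()
    if not sinogram.fully_valid:
        raise InvalidSinogramError(
            "sinogram has invalid entries; run completion (linear_interpolate "
            "or unet_synthesize) before reconstruction"
        )
    g = sinogram.geometry
    filtered = _filtered_projections(sinogram, config)
    n = g.image_size
    half = (n - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    x = (jj - half) * g.pixel_size
    y = (half - ii) * g.pixel_size
    s0 = (g.n_bins - 1) / 2.0
    out = np.zeros((n, n), dtype=np.float64)
    for v, theta in enumerate(g.angles_rad):
        s = x * np.cos(theta) + y * np.sin(theta)
        k = s / g.bin_spacing + s0
        k0 = np.floor(k).astype(np.int64)
        frac = k - k0
        k0c = np.clip(k0, 0, g.n_bins - 1)
        k1c = np.clip(k0 + 1, 0, g.n_bins - 1)
        inside = (k >= 0) & (k <= g.n_bins - 1)
        proj = filtered[:, v]
        out += np.where(inside, proj[k0c] * (1 - frac) + proj[k1c] * frac, 0.0)
    d_theta = np.deg2rad(g.angle_step_deg)
    out *= d_theta / 2.0  # full 360-degree scan: average conjugate rays
    return ImageSlice(out, g)


def reprojection_consistency(
    sinogram: Sinogram,
    measured_mask: np.ndarray,
    config: FBPConfig | None = None,
) -> float:
    """Physical self-consistency of a completed sinogram, without ground
    truth: reconstruct it with FBP, forward-project the reconstruction, and
    return the RMS mismatch at the *measured* bins.

    A completion that corrupts the object raises this mismatch even though
    the measured bins themselves are untouched, because reconstruction mixes
    every view into every ray.  Used to decide, per scan, whether a learned
    completion actually improved on its classical initialization.
    """
    recon = fbp_reconstruct(sinogram, config or FBPConfig())
    reproj = forward_project(recon, sinogram.geometry)
    diff = reproj.values[measured_mask] - sinogram.values[measured_mask]
    return float(np.sqrt(np.mean(diff**2)))


def _huber_potential(r: np.ndarray, delta: float) -> np.ndarray:
    a = np.abs(r)
    return np.where(a <= delta, 0.5 * r * r, delta * a - 0.5 * delta * delta)


def _huber_grad(r: np.ndarray, delta: float) -> np.ndarray:
    return np.clip(r, -delta, delta)


def _roughness(x: np.ndarray, delta: float):
    """Huber roughness over horizontal+vertical neighbor differences and its
    gradient."""
    dx = np.diff(x, axis=1)
    dy = np.diff(x, axis=0)
    value = _huber_potential(dx, delta).sum() + _huber_potential(dy, delta).sum()
    grad = np.zeros_like(x)
    gx = _huber_grad(dx, delta)
    gy = _huber_grad(dy, delta)
    grad[:, :-1] -= gx
    grad[:, 1:] += gx
    grad[:-1, :] -= gy
    grad[1:, :] += gy
    return value, grad


class DivergenceError(RuntimeError):
    pass


def pwls_reconstruct(
    sinogram: Sinogram,
    config: IRConfig | None = None,
    init: ImageSlice | None = None,
    callback=None,
) -> ImageSlice:
    """Penalized weighted-least-squares reconstruction (comparison baseline).

    Minimizes ``0.5 ||P x - y||^2 + beta * sum psi_delta(neighbor diffs)``
    where ``psi_delta`` is the Huber potential, by monotone gradient descent
    with backtracking (the step is halved until the objective decreases, and
    gently grown after each accepted step).  The weighting W is the identity;
    the projector adjoint is exact, so every accepted step decreases the
    objective.

    ``init`` defaults to the FBP image of the same sinogram.
    """
    if config is None:
        config = IRConfig()
    if not sinogram.fully_valid:
        raise InvalidSinogramError("sinogram has invalid entries; complete it first")
    g = sinogram.geometry
    y = sinogram.values
    x = (init.values.copy() if init is not None else fbp_reconstruct(sinogram).values)
    beta, delta = config.smoothness, config.edge_preservation

    def objective_and_grad(xv: np.ndarray):
        img = ImageSlice(xv, g)
        resid = forward_project(img, g).values - y
        data = 0.5 * np.sum(resid**2)
        grad_data = back_project_adjoint(Sinogram(resid, g)).values
        rough, grad_rough = _roughness(xv, delta)
        return data + beta * rough, grad_data + beta * grad_rough

    obj, grad = objective_and_grad(x)
    gnorm2 = np.sum(grad**2)
    step = 1.0 if gnorm2 == 0 else obj / (gnorm2 + 1e-30)
    for it in range(config.n_iterations):
        if gnorm2 == 0:
            break
        accepted = False
        for _ in range(40):
            x_new = x - step * grad
            obj_new, grad_new = objective_and_grad(x_new)
            if obj_new <= obj + 1e-12 * max(1.0, abs(obj)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            raise DivergenceError(
                f"PWLS line search failed at iteration {it}: objective {obj:.6g} "
                f"could not be decreased (last trial {obj_new:.6g})"
            )
        x, obj, grad = x_new, obj_new, grad_new
        gnorm2 = np.sum(grad**2)
        step *= 1.5
        if callback is not None:
            callback(it, obj, x)
    return ImageSlice(x, g)
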
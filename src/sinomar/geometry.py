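"""Scan geometry, core data containers and the line-integral forward projector.

Conventions (fixed throughout the package):

* Image pixel ``(0, 0)`` is the top-left array element; the isocenter sits at
  the grid center ``((N-1)/2, (N-1)/2)``.
* Physical coordinates: ``x`` increases with column index, ``y`` increases
  upward (i.e. with *decreasing* row index).
* Projection angles are measured counter-clockwise from the +x axis; views are
  ordered by increasing angle.
* Detector coordinate ``s = 0`` lies at the detector center; bin ``k`` sits at
  ``s_k = (k - (n_bins - 1)/2) * bin_spacing``.
* A sinogram is indexed ``(bin, view)``.

The projector is a 2-D parallel-beam line integrator: each ray is sampled at
half-pixel steps and the attenuation map is interpolated bilinearly along the
ray (a Joseph-style scheme).  It is exactly linear in the image, which the
whole pipeline (metal-trace location, simulation, PWLS) relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ScanGeometry",
    "ImageSlice",
    "Sinogram",
    "forward_project",
    "back_project_adjoint",
    "analytic_disk_sinogram",
]


class GeometryError(ValueError):
    """Configuration/shape mismatch between arrays and a ScanGeometry."""


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam full-scan acquisition geometry.

    Parameters
    ----------
    n_views:
        Number of projection angles.
    angle_step_deg:
        Angular increment between consecutive views, in degrees.  For a
        full-scan geometry ``n_views * angle_step_deg`` must equal 360.
    n_bins:
        Number of detector bins.
    bin_spacing:
        Detector bin width, in the same physical units as ``pixel_size``.
    image_size:
        Side length of the square reconstruction grid, in pixels.
    pixel_size:
        Physical width of one image pixel.
    """

    n_views: int = 360
    angle_step_deg: float = 1.0
    n_bins: int = 180
    bin_spacing: float = 1.0
    image_size: int = 128
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_bins < 2 or self.image_size < 1:
            raise GeometryError("n_views, n_bins and image_size must be positive")
        if not np.isclose(self.n_views * self.angle_step_deg, 360.0):
            raise GeometryError(
                f"full-scan geometry requires n_views * angle_step_deg == 360, "
                f"got {self.n_views} * {self.angle_step_deg}"
            )
        # The detector must cover the inscribed field-of-view circle; object
        # support is required to lie inside that circle (no truncation).
        if self.n_bins * self.bin_spacing < self.image_size * self.pixel_size:
            raise GeometryError(
                "detector does not cover the field-of-view circle: "
                f"{self.n_bins} bins * {self.bin_spacing} < "
                f"{self.image_size} px * {self.pixel_size}"
            )

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * self.angle_step_deg

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)

    @property
    def bin_positions(self) -> np.ndarray:
        """Detector coordinates s_k of the bin centers."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing

    @property
    def fov_radius(self) -> float:
        """Radius of the inscribed field-of-view circle (physical units)."""
        return self.image_size * self.pixel_size / 2.0

    def with_views(self, n_views: int) -> "ScanGeometry":
        """Same detector/grid with a different full-scan angular sampling."""
        return ScanGeometry(
            n_views=n_views,
            angle_step_deg=360.0 / n_views,
            n_bins=self.n_bins,
            bin_spacing=self.bin_spacing,
            image_size=self.image_size,
            pixel_size=self.pixel_size,
        )


@dataclass
class ImageSlice:
    """2-D attenuation map on the reconstruction grid."""

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.geometry.image_size
        if self.values.shape != (n, n):
            raise GeometryError(
                f"image shape {self.values.shape} does not match geometry grid {(n, n)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("image contains non-finite values")

    def copy(self) -> "ImageSlice":
        return ImageSlice(self.values.copy(), self.geometry)


@dataclass
class Sinogram:
    """Line integrals indexed ``(bin, view)`` with an optional validity mask.

    ``valid_mask`` is ``False`` where data are missing (removed views or metal
    tracks); consumers must treat those entries as undefined.
    """

    values: np.ndarray
    geometry: ScanGeometry
    valid_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_bins, self.geometry.n_views)
        if self.values.shape != expected:
            raise GeometryError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(expected, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != expected:
                raise GeometryError("valid_mask shape does not match sinogram")

    @property
    def fully_valid(self) -> bool:
        return bool(self.valid_mask.all())

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry, self.valid_mask.copy())


def _ray_sampling(geometry: ScanGeometry, step_frac: float = 0.5):
    """Sample offsets t along a ray and the integration step (physical units)."""
    step = geometry.pixel_size * step_frac
    half_diag = geometry.image_size * geometry.pixel_size * np.sqrt(2.0) / 2.0
    n_t = int(np.ceil(2.0 * half_diag / step)) + 1
    t = (np.arange(n_t) - (n_t - 1) / 2.0) * step
    return t, step


def _ray_index_coords(geometry: ScanGeometry, theta: float, t: np.ndarray):
    """Array (row, col) coordinates of all (s, t) sample points for one view."""
    s = geometry.bin_positions
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # p(s, t) = s * n + t * d with n = (cos, sin), d = (-sin, cos)
    x = s[:, None] * cos_t - t[None, :] * sin_t
    y = s[:, None] * sin_t + t[None, :] * cos_t
    half = (geometry.image_size - 1) / 2.0
    col = x / geometry.pixel_size + half
    row = half - y / geometry.pixel_size
    return row, col


def forward_project(image: ImageSlice, geometry: ScanGeometry | None = None) -> Sinogram:
    """Line-integral projection of an attenuation map at every (bin, view).

    Linear in the image.  Returns a fully valid sinogram.
    """
    if geometry is None:
        geometry = image.geometry
    if image.geometry.image_size != geometry.image_size or not np.isclose(
        image.geometry.pixel_size, geometry.pixel_size
    ):
        raise GeometryError("image grid does not match projection geometry")
    t, step = _ray_sampling(geometry)
    sino = np.empty((geometry.n_bins, geometry.n_views), dtype=np.float64)
    vals = image.values
    for v, theta in enumerate(geometry.angles_rad):
        row, col = _ray_index_coords(geometry, theta, t)
        samples = map_coordinates(vals, [row, col], order=1, mode="grid-constant", cval=0.0)
        sino[:, v] = samples.sum(axis=1) * step
    return Sinogram(sino, geometry)


def back_project_adjoint(sinogram: Sinogram) -> ImageSlice:
    """Exact adjoint (transpose) of :func:`forward_project`.

    Satisfies <forward(x), y> = <x, adjoint(y)> to floating tolerance, which is
    what iterative reconstruction needs for guaranteed descent.  This is *not*
    the filtered-backprojection backprojector (no filtering, no angular
    weighting).
    """
    g = sinogram.geometry
    t, step = _ray_sampling(g)
    n = g.image_size
    out = np.zeros(n * n, dtype=np.float64)
    for v, theta in enumerate(g.angles_rad):
        row, col = _ray_index_coords(g, theta, t)
        vals = np.broadcast_to(sinogram.values[:, v, None] * step, row.shape).ravel()
        r, c = row.ravel(), col.ravel()
        r0 = np.floor(r).astype(np.int64)
        c0 = np.floor(c).astype(np.int64)
        fr, fc = r - r0, c - c0
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr, cc = r0 + dr, c0 + dc
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            np.add.at(out, rr[ok] * n + cc[ok], vals[ok] * w[ok])
    return ImageSlice(out.reshape(n, n), g)


def analytic_disk_sinogram(
    center: tuple[float, float],
    radius: float,
    attenuation: float,
    geometry: ScanGeometry,
) -> Sinogram:
    """Closed-form sinogram of a uniform disk (test oracle for the projector).

    For a disk of radius ``r`` and attenuation ``mu`` centered at physical
    coordinates ``(cx, cy)``, the line integral at detector coordinate ``s``
    and angle ``theta`` is ``2 mu sqrt(r^2 - (s - s0)^2)`` for
    ``|s - s0| < r`` with trace center ``s0 = cx cos(theta) + cy sin(theta)``,
    and zero otherwise.
    """
    cx, cy = center
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if np.hypot(cx, cy) + radius > geometry.fov_radius + 1e-9:
        raise ValueError("disk extends outside the field of view")
    s = geometry.bin_positions[:, None]
    theta = geometry.angles_rad[None, :]
    s0 = cx * np.cos(theta) + cy * np.sin(theta)
    d2 = radius**2 - (s - s0) ** 2
    vals = 2.0 * attenuation * np.sqrt(np.clip(d2, 0.0, None))
    return Sinogram(vals, geometry)
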
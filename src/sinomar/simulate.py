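"""Synthetic specimen phantoms and the paired-artifact simulation chain.

The clinical ground truth this method was designed for (micro-CT scans of
resected breast specimens with a needle marker) is emulated by
piecewise-constant ellipse phantoms with two soft-tissue classes —
adipose-like low attenuation and fibroglandular-like higher attenuation —
plus an embedded high-attenuation metal wire.  The simulation chain mirrors
the acquisition it stands in for: forward projection of the metal-embedded
image per Beer's law at 1-degree steps over 360 degrees, then x4 angular
decimation (360 -> 90 views) to emulate the reduced scan time.  Beam
hardening and scatter are deliberately not simulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

from .completion import downsample_views
from .geometry import ImageSlice, ScanGeometry, Sinogram, forward_project
from .metal import MetalMask, MetalTrace, compute_metal_trace
from .recon import FBPConfig, fbp_reconstruct

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "MetalWireSpec",
    "SimPair",
    "generate_phantom",
    "embed_metal",
    "simulate_pair",
    "generate_dataset",
    "random_phantom_spec",
    "random_wire_spec",
    "stratified_wire_sampler",
    "default_metal_threshold",
    "ADIPOSE_MU",
    "FIBROGLANDULAR_MU",
    "METAL_MU",
]

# Default attenuation values (arbitrary consistent units).  Soft tissue is
# order 0.2-0.4; the metal wire is two orders of magnitude above it so that
# threshold segmentation is unambiguous.
ADIPOSE_MU = 0.20
FIBROGLANDULAR_MU = 0.40
METAL_MU = 50.0


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class Ellipse:
    """Axis lengths are semi-axes; center in physical coordinates (x right,
    y up, origin at isocenter); angle counter-clockwise in degrees."""

    cx: float
    cy: float
    a: float
    b: float
    angle_deg: float
    value: float


@dataclass(frozen=True)
class PhantomSpec:
    """Soft-tissue phantom: a background outline ellipse plus tissue ellipses
    (later entries overwrite earlier ones), with optional smoothed texture
    noise inside the outline.  Metal is *not* part of the phantom — it is
    embedded separately so the metal-free ground truth exists."""

    background: Ellipse
    tissues: tuple[Ellipse, ...] = ()
    texture_noise: float = 0.0
    texture_smoothing: float = 2.0
    seed: int = 0

    def all_ellipses(self) -> tuple[Ellipse, ...]:
        return (self.background, *self.tissues)

    def max_tissue_value(self) -> float:
        return max(e.value for e in self.all_ellipses())

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MetalWireSpec:
    """Metal wire mimicking a needle marker: a disk (cross-section of a wire
    normal to the slice) or a line-segment capsule (wire lying in-slice).
    Sizes in pixels; attenuation far above tissue."""

    shape: str = "disk"
    cx: float = 0.0
    cy: float = 0.0
    radius: float = 3.0
    length: float = 20.0
    width: float = 2.0
    angle_deg: float = 0.0
    attenuation: float = METAL_MU

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "capsule"):
            raise SpecError("wire shape must be 'disk' or 'capsule'")
        if self.attenuation <= 0:
            raise SpecError("wire attenuation must be positive")

    def extent(self) -> float:
        """Radius of the circumscribing circle around the wire."""
        if self.shape == "disk":
            return self.radius
        return self.length / 2.0 + self.width / 2.0

    def to_dict(self) -> dict:
        return asdict(self)


def default_metal_threshold(max_tissue: float, metal_attenuation: float) -> float:
    """Segmentation threshold: midpoint between the strongest soft tissue and
    the metal attenuation (exact on synthetic data)."""
    return 0.5 * (max_tissue + metal_attenuation)


def _grid_xy(geometry: ScanGeometry):
    n, px = geometry.image_size, geometry.pixel_size
    half = (n - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    return (jj - half) * px, (half - ii) * px


def _inside_fov(geometry: ScanGeometry, cx: float, cy: float, extent: float) -> bool:
    return np.hypot(cx, cy) + extent <= geometry.fov_radius + 1e-9


def _ellipse_mask(e: Ellipse, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    t = np.deg2rad(e.angle_deg)
    dx, dy = x - e.cx, y - e.cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, geometry: ScanGeometry) -> ImageSlice:
    """Rasterize the phantom onto the reconstruction grid.

    Later structures overwrite earlier ones.  Texture noise (Gaussian,
    smoothed by ``texture_smoothing`` pixels, seeded) is added inside the
    outline support.  Deterministic under a fixed spec seed.
    """
    for e in spec.all_ellipses():
        if e.value < 0:
            raise SpecError("attenuations must be non-negative")
        if not _inside_fov(geometry, e.cx, e.cy, max(e.a, e.b)):
            raise SpecError(f"ellipse at ({e.cx}, {e.cy}) extends outside the field of view")
    x, y = _grid_xy(geometry)
    img = np.zeros_like(x)
    support = None
    for k, e in enumerate(spec.all_ellipses()):
        m = _ellipse_mask(e, x, y)
        img[m] = e.value
        if k == 0:
            support = m
    if spec.texture_noise > 0 and support is not None:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, 1.0, img.shape)
        if spec.texture_smoothing > 0:
            noise = gaussian_filter(noise, spec.texture_smoothing)
            noise /= max(noise.std(), 1e-12)
        img[support] += spec.texture_noise * noise[support]
        np.clip(img, 0.0, None, out=img)
    return ImageSlice(img, geometry)


def embed_metal(image: ImageSlice, wire: MetalWireSpec) -> tuple[ImageSlice, MetalMask]:
    """Set the wire pixels to the wire attenuation; return the modified image
    and the exact ground-truth metal mask."""
    g = image.geometry
    if not _inside_fov(g, wire.cx, wire.cy, wire.extent()):
        raise SpecError("metal wire extends outside the field of view")
    x, y = _grid_xy(g)
    px = g.pixel_size
    if wire.shape == "disk":
        support = (x - wire.cx) ** 2 + (y - wire.cy) ** 2 <= (wire.radius * px) ** 2
    else:
        t = np.deg2rad(wire.angle_deg)
        dx, dy = x - wire.cx, y - wire.cy
        u = dx * np.cos(t) + dy * np.sin(t)
        v = -dx * np.sin(t) + dy * np.cos(t)
        hl, hw = wire.length * px / 2.0, wire.width * px / 2.0
        d_along = np.clip(np.abs(u) - hl, 0.0, None)
        support = d_along**2 + v**2 <= hw**2
    out = image.copy()
    out.values[support] = wire.attenuation
    return out, MetalMask(support, out.values[support])


@dataclass
class SimPair:
    """One simulated training/testing case: the full artifact bundle."""

    ground_truth: ImageSlice
    dense_sinogram: Sinogram              # metal-free, full angular sampling
    metal_sinogram: Sinogram              # metal-embedded, full angular sampling
    sparse_sinogram: Sinogram             # metal-embedded, decimated views
    metal_mask: MetalMask
    metal_trace: MetalTrace               # on the dense view grid
    artifact_image: ImageSlice            # FBP of the decimated metal sinogram
    spec: PhantomSpec = None
    wire: MetalWireSpec | None = None
    decimation_factor: int = 1


def _maybe_add_noise(sino: Sinogram, rel_noise: float, rng: np.random.Generator) -> Sinogram:
    if rel_noise <= 0:
        return sino
    scale = rel_noise * float(np.abs(sino.values).max())
    out = sino.copy()
    out.values += rng.normal(0.0, scale, out.values.shape)
    return out


def simulate_pair(
    spec: PhantomSpec,
    wire: MetalWireSpec | None,
    geometry: ScanGeometry,
    decimation_factor: int = 4,
    fbp_config: FBPConfig | None = None,
    projection_noise: float = 0.0,
    noise_seed: int = 0,
) -> SimPair:
    """Simulate one paired case: ground truth, dense/metal/sparse sinograms,
    metal trace, and the FBP artifact image from the decimated metal
    sinogram.  ``projection_noise`` optionally adds Gaussian noise on the
    line integrals (relative to the sinogram peak; off by default)."""
    if geometry.n_views % decimation_factor:
        raise SpecError("decimation factor must divide n_views")
    rng = np.random.default_rng(noise_seed)
    truth = generate_phantom(spec, geometry)
    dense = _maybe_add_noise(forward_project(truth, geometry), projection_noise, rng)
    if wire is not None:
        embedded, mask = embed_metal(truth, wire)
        metal_sino = _maybe_add_noise(forward_project(embedded, geometry), projection_noise, rng)
        trace = compute_metal_trace(mask, geometry)
    else:
        mask = MetalMask(np.zeros(truth.values.shape, bool), np.empty(0))
        metal_sino = dense
        trace = MetalTrace(np.zeros(dense.values.shape, bool))
    sparse = downsample_views(metal_sino, decimation_factor)
    artifact = fbp_reconstruct(sparse, fbp_config or FBPConfig())
    return SimPair(
        ground_truth=truth,
        dense_sinogram=dense,
        metal_sinogram=metal_sino,
        sparse_sinogram=sparse,
        metal_mask=mask,
        metal_trace=trace,
        artifact_image=artifact,
        spec=spec,
        wire=wire,
        decimation_factor=decimation_factor,
    )


def random_phantom_spec(rng: np.random.Generator, geometry: ScanGeometry) -> PhantomSpec:
    """Sample a two-tissue-class specimen phantom.

    A large adipose-like outline ellipse fills most of the field of view;
    3-6 fibroglandular-like ellipses and 1-3 darker adipose pockets are
    scattered inside it.  The phantoms are piecewise-constant (texture noise
    off): the completion task is then well-posed — edge-induced sinogram
    structure is systematic and learnable — whereas unstructured
    high-frequency texture is not recoverable from 90 views.
    """
    R = geometry.fov_radius
    bg_a = rng.uniform(0.62, 0.78) * R
    bg_b = rng.uniform(0.62, 0.78) * R
    bg = Ellipse(
        cx=rng.uniform(-0.05, 0.05) * R,
        cy=rng.uniform(-0.05, 0.05) * R,
        a=bg_a,
        b=bg_b,
        angle_deg=rng.uniform(0, 180),
        value=ADIPOSE_MU,
    )
    tissues = []
    inner = 0.55 * min(bg_a, bg_b)
    for value, lo_n, hi_n, size in (
        (FIBROGLANDULAR_MU, 3, 6, 0.28),
        (0.6 * ADIPOSE_MU, 1, 3, 0.18),
    ):
        for _ in range(rng.integers(lo_n, hi_n + 1)):
            r = rng.uniform(0, inner)
            phi = rng.uniform(0, 2 * np.pi)
            tissues.append(
                Ellipse(
                    cx=bg.cx + r * np.cos(phi),
                    cy=bg.cy + r * np.sin(phi),
                    a=rng.uniform(0.3, 1.0) * size * R,
                    b=rng.uniform(0.3, 1.0) * size * R,
                    angle_deg=rng.uniform(0, 180),
                    value=value * rng.uniform(0.9, 1.1),
                )
            )
    return PhantomSpec(
        background=bg,
        tissues=tuple(tissues),
        texture_noise=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def random_wire_spec(rng: np.random.Generator, geometry: ScanGeometry) -> MetalWireSpec:
    """Sample a needle-marker wire: a small metal disk near the phantom
    center (radius 2-4 px, attenuation far above tissue)."""
    R = geometry.fov_radius
    r = rng.uniform(0, 0.3) * R
    phi = rng.uniform(0, 2 * np.pi)
    return MetalWireSpec(
        shape="disk",
        cx=r * np.cos(phi),
        cy=r * np.sin(phi),
        radius=float(rng.uniform(2.0, 4.0)),
        attenuation=METAL_MU,
    )


def stratified_wire_sampler(n_cases: int, geometry: ScanGeometry):
    """Training-set wire sampler covering a (radius x eccentricity) grid.

    Random placement under-represents the corners of the wire parameter
    space (e.g. wide wires near the rotation center, whose traces are the
    hardest to synthesize); for *training* data the wires are therefore laid
    out on a stratified grid of radii 2-4 px and center offsets spanning the
    deployment range, with random azimuth.  Test cases keep the random
    sampler — the stratification is experimental design for training
    coverage, not a change of the evaluation distribution.
    """
    radii = (2.0, 2.7, 3.4, 4.0)
    rhos_frac = (0.03, 0.11, 0.19, 0.27)  # of the field-of-view diameter
    grid = [(r, f) for r in radii for f in rhos_frac]
    reps = (n_cases + len(grid) - 1) // len(grid)
    sequence = iter((grid * reps)[:n_cases])

    def sampler(rng: np.random.Generator, geom: ScanGeometry) -> MetalWireSpec:
        radius, frac = next(sequence)
        rho = frac * 2.0 * geom.fov_radius
        phi = rng.uniform(0, 2 * np.pi)
        return MetalWireSpec(
            shape="disk",
            cx=rho * np.cos(phi),
            cy=rho * np.sin(phi),
            radius=radius,
            attenuation=METAL_MU,
        )

    return sampler


def _write_case(grp: h5py.Group, pair: SimPair) -> None:
    grp.create_dataset("ground_truth", data=pair.ground_truth.values)
    grp.create_dataset("dense_sinogram", data=pair.dense_sinogram.values)
    grp.create_dataset("metal_sinogram", data=pair.metal_sinogram.values)
    grp.create_dataset("sparse_sinogram", data=pair.sparse_sinogram.values)
    grp.create_dataset("metal_mask", data=pair.metal_mask.support.astype(np.uint8))
    grp.create_dataset("metal_values", data=pair.metal_mask.metal_values)
    grp.create_dataset("metal_trace", data=pair.metal_trace.support.astype(np.uint8))
    grp.create_dataset("artifact_image", data=pair.artifact_image.values)


def generate_dataset(
    n_cases: int,
    spec_sampler,
    geometry: ScanGeometry,
    out_path,
    seed: int = 0,
    wire_sampler=None,
    decimation_factor: int = 4,
    n_train: int | None = None,
) -> str:
    """Simulate ``n_cases`` phantoms and write them to an HDF5 file.

    ``spec_sampler(rng, geometry)`` returns a PhantomSpec per case;
    ``wire_sampler`` likewise (None for metal-free cases).  The first
    ``n_train`` cases (default: all but two) are labelled ``train``, the rest
    ``test``, mirroring a train/test split of specimen scans.  A JSON
    manifest of every spec and seed is stored as a file attribute;
    byte-identical for a fixed seed.
    """
    if n_cases < 1:
        raise SpecError("n_cases must be >= 1")
    if n_train is None:
        n_train = max(1, n_cases - 2)
    rng = np.random.default_rng(seed)
    manifest = {"seed": int(seed), "decimation_factor": int(decimation_factor), "cases": []}
    with h5py.File(out_path, "w") as f:
        g = geometry
        for key, val in (
            ("n_views", g.n_views),
            ("angle_step_deg", g.angle_step_deg),
            ("n_bins", g.n_bins),
            ("bin_spacing", g.bin_spacing),
            ("image_size", g.image_size),
            ("pixel_size", g.pixel_size),
        ):
            f.attrs[key] = val
        for i in range(n_cases):
            case_seed = int(rng.integers(0, 2**31 - 1))
            case_rng = np.random.default_rng(case_seed)
            spec = spec_sampler(case_rng, geometry)
            wire = wire_sampler(case_rng, geometry) if wire_sampler is not None else None
            pair = simulate_pair(spec, wire, geometry, decimation_factor)
            group = "train" if i < n_train else "test"
            grp = f.create_group(f"case_{i:03d}")
            grp.attrs["group"] = group
            grp.attrs["seed"] = case_seed
            _write_case(grp, pair)
            manifest["cases"].append(
                {
                    "index": i,
                    "group": group,
                    "seed": case_seed,
                    "spec": spec.to_dict(),
                    "wire": wire.to_dict() if wire is not None else None,
                }
            )
        f.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
    return str(out_path)
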
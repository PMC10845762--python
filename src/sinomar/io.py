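"""Reading and writing sinograms, images and masks (HDF5 and TIFF).

HDF5 layout: datasets ``/sinogram`` (+ ``/valid_mask``) or ``/image``, with
the scan geometry stored as file attributes (``n_views``, ``angle_step_deg``,
``n_bins``, ``bin_spacing``, ``image_size``, ``pixel_size``).  Metal masks
and traces are stored as uint8 datasets ``/metal_mask`` / ``/metal_trace``.
TIFF holds bare arrays (one slice or sinogram per page) without geometry.
"""

from __future__ import annotations

import h5py
import numpy as np
import tifffile

from .geometry import ImageSlice, ScanGeometry, Sinogram

__all__ = [
    "write_sinogram",
    "read_sinogram",
    "write_image",
    "read_image",
    "write_tiff",
    "read_tiff",
]

_GEOM_ATTRS = ("n_views", "angle_step_deg", "n_bins", "bin_spacing", "image_size", "pixel_size")


def _write_geometry(f: h5py.File, g: ScanGeometry) -> None:
    for name in _GEOM_ATTRS:
        f.attrs[name] = getattr(g, name)


def _read_geometry(f: h5py.File) -> ScanGeometry:
    kwargs = {name: f.attrs[name] for name in _GEOM_ATTRS}
    kwargs["n_views"] = int(kwargs["n_views"])
    kwargs["n_bins"] = int(kwargs["n_bins"])
    kwargs["image_size"] = int(kwargs["image_size"])
    return ScanGeometry(**kwargs)


def write_sinogram(path, sinogram: Sinogram, extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sinogram", data=sinogram.values)
        f.create_dataset("valid_mask", data=sinogram.valid_mask.astype(np.uint8))
        _write_geometry(f, sinogram.geometry)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def read_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        geometry = _read_geometry(f)
        values = f["sinogram"][()]
        mask = f["valid_mask"][()].astype(bool) if "valid_mask" in f else None
    return Sinogram(values, geometry, mask)


def write_image(path, image: ImageSlice, extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=image.values)
        _write_geometry(f, image.geometry)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def read_image(path) -> ImageSlice:
    with h5py.File(path, "r") as f:
        geometry = _read_geometry(f)
        values = f["image"][()]
    return ImageSlice(values, geometry)


def write_tiff(path, array: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)
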
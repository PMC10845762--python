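"""Shared fixtures: small scan geometries, analytic phantoms, and one
session-scope simulated-and-trained stack used by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

import sinomar as sm
from sinomar import dataprep



def aa_disk(n: int, radius: float, center=(0.0, 0.0), value: float = 1.0, ss: int = 8) -> np.ndarray:
    """Anti-aliased (area-sampled) rasterization of a uniform disk, the grid
    representation of the continuous disk the analytic sinogram describes."""
    big = np.zeros((n * ss, n * ss))
    half = (n * ss - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n * ss), np.arange(n * ss))
    x = (jj - half) / ss
    y = (half - ii) / ss
    big[(x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2] = value
    return big.reshape(n, ss, n, ss).mean(axis=(1, 3))


@pytest.fixture(scope="session")
def geom_small() -> sm.ScanGeometry:
    """Desk-scale test geometry: 64x64 grid, 96 bins, 120 views over 360 deg."""
    return sm.ScanGeometry(n_views=120, angle_step_deg=3.0, n_bins=96, image_size=64)


@pytest.fixture(scope="session")
def geom_tiny() -> sm.ScanGeometry:
    """Very small geometry for expensive operators (adjoints, PWLS)."""
    return sm.ScanGeometry(n_views=45, angle_step_deg=8.0, n_bins=48, image_size=32)


@pytest.fixture(scope="session")
def geom_default() -> sm.ScanGeometry:
    """Reference desk-scale geometry: 128x128, 180 bins, 360 views at 1 deg."""
    return sm.ScanGeometry()


@pytest.fixture(scope="session")
def two_class_spec() -> sm.PhantomSpec:
    """A fixed two-tissue-class phantom spec (no texture noise)."""
    return sm.PhantomSpec(
        background=sm.Ellipse(0.0, 1.0, 24.0, 20.0, 10.0, 0.2),
        tissues=(
            sm.Ellipse(-6.0, 3.0, 7.0, 5.0, 30.0, 0.4),
            sm.Ellipse(8.0, -4.0, 5.0, 4.0, 120.0, 0.38),
            sm.Ellipse(2.0, 9.0, 3.0, 3.0, 0.0, 0.12),
        ),
        texture_noise=0.0,
    )


@pytest.fixture(scope="session")
def phantom_small(two_class_spec, geom_small) -> sm.ImageSlice:
    return sm.generate_phantom(two_class_spec, geom_small)


@pytest.fixture(scope="session")
def trained_stack():
    """The canonical desk-scale experiment (simulate a paired dataset with
    stratified training wires, train both network stages) at the reference
    geometry.  Session-scoped: this is the expensive fixture behind the
    learning and end-to-end ordering tests (10-15 CPU-minutes)."""
    import os
    import tempfile

    geometry = sm.ScanGeometry()
    path = os.path.join(tempfile.mkdtemp(), "dataset.h5")
    return dataprep.simulate_and_train(geometry, path, seed=7)
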
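"""Phantom generation, metal embedding and the paired-artifact simulation."""

import json

import h5py
import numpy as np
import pytest

import sinomar as sm
from sinomar.simulate import SpecError


class TestGeneratePhantom:
    def test_zero_value_background_gives_zero_image(self, geom_small):
        spec = sm.PhantomSpec(background=sm.Ellipse(0, 0, 20, 15, 0, 0.0))
        img = sm.generate_phantom(spec, geom_small)
        assert np.all(img.values == 0.0)

    def test_ellipse_area_matches_analytic(self, geom_default):
        """Pixel count of a rasterized ellipse is within 2% of pi*a*b."""
        a, b = 40.0, 25.0
        spec = sm.PhantomSpec(background=sm.Ellipse(0, 0, a, b, 30.0, 1.0))
        img = sm.generate_phantom(spec, geom_default)
        count = (img.values == 1.0).sum()
        assert abs(count - np.pi * a * b) < 0.02 * np.pi * a * b

    def test_later_structures_overwrite_earlier(self, geom_small):
        spec = sm.PhantomSpec(
            background=sm.Ellipse(0, 0, 20, 20, 0, 0.2),
            tissues=(sm.Ellipse(0, 0, 5, 5, 0, 0.9),),
        )
        img = sm.generate_phantom(spec, geom_small)
        assert img.values[32, 32] == 0.9

    def test_seeded_texture_deterministic(self, geom_small):
        spec = sm.PhantomSpec(
            background=sm.Ellipse(0, 0, 20, 20, 0, 0.2), texture_noise=0.05, seed=4
        )
        a = sm.generate_phantom(spec, geom_small)
        b = sm.generate_phantom(spec, geom_small)
        assert np.array_equal(a.values, b.values)
        assert a.values.std() > 0

    def test_structure_outside_fov_rejected(self, geom_small):
        spec = sm.PhantomSpec(background=sm.Ellipse(20, 0, 20, 10, 0, 0.2))
        with pytest.raises(SpecError):
            sm.generate_phantom(spec, geom_small)


class TestEmbedMetal:
    def test_zero_radius_wire_changes_nothing(self, phantom_small):
        wire = sm.MetalWireSpec(shape="disk", cx=0.3, cy=0.3, radius=0.0)
        out, mask = sm.embed_metal(phantom_small, wire)
        assert mask.is_empty
        assert np.array_equal(out.values, phantom_small.values)

    def test_disk_wire_mask_and_values(self, phantom_small, geom_small):
        wire = sm.MetalWireSpec(shape="disk", cx=4.0, cy=-2.0, radius=3.0, attenuation=50.0)
        out, mask = sm.embed_metal(phantom_small, wire)
        n, px = geom_small.image_size, geom_small.pixel_size
        half = (n - 1) / 2.0
        jj, ii = np.meshgrid(np.arange(n), np.arange(n))
        x, y = (jj - half) * px, (half - ii) * px
        member = (x - wire.cx) ** 2 + (y - wire.cy) ** 2 <= (wire.radius * px) ** 2
        assert np.array_equal(mask.support, member)
        assert np.all(out.values[mask.support] == 50.0)

    def test_capsule_wire_rasterizes(self, phantom_small):
        wire = sm.MetalWireSpec(shape="capsule", cx=0, cy=0, length=14, width=2,
                                angle_deg=25.0, attenuation=50.0)
        out, mask = sm.embed_metal(phantom_small, wire)
        assert mask.support.sum() > 10
        assert np.all(out.values[mask.support] == 50.0)

    def test_consistent_with_threshold_segmentation(self, phantom_small):
        wire = sm.MetalWireSpec(shape="disk", cx=4.0, cy=-2.0, radius=3.0, attenuation=50.0)
        out, mask = sm.embed_metal(phantom_small, wire)
        threshold = sm.default_metal_threshold(phantom_small.values.max(), 50.0)
        seg = sm.segment_metal(out, threshold)
        assert np.array_equal(seg.support, mask.support)

    def test_wire_outside_fov_rejected(self, phantom_small):
        with pytest.raises(SpecError):
            sm.embed_metal(phantom_small, sm.MetalWireSpec(cx=31.0, cy=0, radius=3.0))


class TestSimulatePair:
    def test_decimation_produces_quarter_views(self, two_class_spec, geom_small):
        pair = sm.simulate_pair(two_class_spec, None, geom_small, decimation_factor=4)
        assert pair.sparse_sinogram.values.shape == (96, 30)
        assert pair.dense_sinogram.values.shape == (96, 120)

    def test_no_artifact_sources_reduces_to_plain_fbp(self, two_class_spec, geom_small):
        pair = sm.simulate_pair(two_class_spec, None, geom_small, decimation_factor=1)
        plain = sm.fbp_reconstruct(pair.dense_sinogram)
        assert np.array_equal(pair.artifact_image.values, plain.values)
        # dense-view FBP agrees with the generating phantom
        rel = sm.rmse(pair.artifact_image.values, pair.ground_truth.values)
        assert rel < 0.05 * pair.ground_truth.values.max()

    def test_metal_produces_streaks(self, two_class_spec, geom_small):
        wire = sm.MetalWireSpec(shape="disk", cx=4.0, cy=-2.0, radius=3.0, attenuation=50.0)
        pair = sm.simulate_pair(two_class_spec, wire, geom_small, decimation_factor=4)
        tissue_max = pair.ground_truth.values.max()
        outside = ~pair.metal_mask.support
        assert (pair.artifact_image.values[outside] > tissue_max).sum() > 0

    def test_wire_growth_expands_trace(self, two_class_spec, geom_small):
        areas = []
        for r in (2.0, 3.0, 4.5):
            wire = sm.MetalWireSpec(shape="disk", cx=4.0, cy=-2.0, radius=r, attenuation=50.0)
            pair = sm.simulate_pair(two_class_spec, wire, geom_small, decimation_factor=4)
            areas.append(pair.metal_trace.support.sum())
        assert areas[0] < areas[1] < areas[2]

    def test_decimated_views_match_dense_at_retained_angles(self, two_class_spec, geom_small):
        wire = sm.MetalWireSpec(shape="disk", cx=4.0, cy=-2.0, radius=3.0, attenuation=50.0)
        pair = sm.simulate_pair(two_class_spec, wire, geom_small, decimation_factor=4)
        assert np.array_equal(pair.sparse_sinogram.values, pair.metal_sinogram.values[:, ::4])


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory, geom_small):
    path = tmp_path_factory.mktemp("ds") / "tiny.h5"
    sm.generate_dataset(
        3, sm.random_phantom_spec, geom_small, path, seed=5,
        wire_sampler=sm.random_wire_spec, decimation_factor=4, n_train=2,
    )
    return path


class TestGenerateDataset:
    def test_group_split(self, tiny_dataset):
        with h5py.File(tiny_dataset) as f:
            groups = [f[k].attrs["group"] for k in sorted(f) if k.startswith("case_")]
        assert groups == ["train", "train", "test"]

    def test_manifest_reproducible(self, tmp_path, geom_small, tiny_dataset):
        other = tmp_path / "again.h5"
        sm.generate_dataset(
            3, sm.random_phantom_spec, geom_small, other, seed=5,
            wire_sampler=sm.random_wire_spec, decimation_factor=4, n_train=2,
        )
        with h5py.File(tiny_dataset) as a, h5py.File(other) as b:
            assert a.attrs["manifest"] == b.attrs["manifest"]
            manifest = json.loads(a.attrs["manifest"])
        assert len(manifest["cases"]) == 3

    def test_cases_satisfy_mass_conservation(self, tiny_dataset, geom_small):
        from sinomar import dataprep

        _, _, cases = dataprep.load_dataset(tiny_dataset)
        for case in cases:
            sino = case.dense_sinogram
            mass = sino.values.sum(axis=0) * geom_small.bin_spacing
            image_mass = case.ground_truth.values.sum() * geom_small.pixel_size**2
            assert np.all(np.abs(mass - image_mass) < 0.01 * image_mass)
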
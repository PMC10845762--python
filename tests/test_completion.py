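"""View decimation/up-sampling, linear interpolation and network synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sinomar as sm
from sinomar.completion import CompletionError
from sinomar.nn import NetConfig, build_modified_unet


def _sino(values, geom):
    return sm.Sinogram(values, geom)


class TestDownsampleViews:
    def test_360_to_90(self, geom_default):
        sino = _sino(np.random.default_rng(0).random((180, 360)), geom_default)
        out = sm.downsample_views(sino, 4)
        assert out.values.shape == (180, 90)
        assert out.geometry.angle_step_deg == 4.0

    def test_factor_one_is_identity(self, geom_small):
        sino = _sino(np.random.default_rng(1).random((96, 120)), geom_small)
        out = sm.downsample_views(sino, 1)
        assert np.array_equal(out.values, sino.values)

    def test_retained_view_indices(self):
        geom = sm.ScanGeometry(n_views=8, angle_step_deg=45.0, n_bins=16, image_size=8)
        vals = np.arange(16 * 8, dtype=float).reshape(16, 8)
        out = sm.downsample_views(_sino(vals, geom), 2)
        assert np.array_equal(out.values, vals[:, [0, 2, 4, 6]])

    def test_non_divisible_factor_rejected(self, geom_small):
        with pytest.raises(CompletionError):
            sm.downsample_views(_sino(np.zeros((96, 120)), geom_small), 7)


class TestUpsampleViewGrid:
    def test_90_to_360_counts(self, geom_default):
        sparse_geom = geom_default.with_views(90)
        sino = _sino(np.random.default_rng(2).random((180, 90)), sparse_geom)
        out = sm.upsample_view_grid(sino, 4)
        assert out.values.shape == (180, 360)
        assert (~out.valid_mask).sum() == 270 * 180
        assert np.array_equal(out.values[:, ::4], sino.values)
        assert out.valid_mask[:, ::4].all()

    def test_factor_one_is_identity(self, geom_small):
        sino = _sino(np.random.default_rng(3).random((96, 120)), geom_small)
        out = sm.upsample_view_grid(sino, 1)
        assert np.array_equal(out.values, sino.values)
        assert out.valid_mask.all()

    @given(factor=st.integers(min_value=2, max_value=6))
    @settings(deadline=None, max_examples=5)
    def test_down_then_up_restores_retained_views(self, factor):
        geom = sm.ScanGeometry(n_views=60 * factor, angle_step_deg=360.0 / (60 * factor),
                               n_bins=24, image_size=16)
        vals = np.random.default_rng(factor).random((24, 60 * factor))
        down = sm.downsample_views(_sino(vals, geom), factor)
        up = sm.upsample_view_grid(down, factor)
        assert np.array_equal(up.values[:, ::factor], vals[:, ::factor])
        assert up.valid_mask[:, ::factor].all()
        assert (~up.valid_mask[:, 1::factor]).all() if factor > 1 else True


class TestLinearInterpolate:
    def test_constant_in_angle_recovered_exactly(self, geom_small):
        profile = np.random.default_rng(4).random(96)
        vals = np.tile(profile[:, None], (1, 120))
        mask = np.zeros((96, 120), bool)
        mask[:, ::2] = True
        out = sm.linear_interpolate(sm.Sinogram(vals, geom_small, mask))
        assert out.valid_mask.all()
        assert np.abs(out.values - vals).max() < 1e-9

    def test_affine_in_view_index_recovered_exactly(self, geom_small):
        """x4 decimation of a sinogram affine in view index: interior views
        (away from the angular wrap seam) are recovered to machine precision."""
        v = np.arange(120, dtype=float)
        rng = np.random.default_rng(5)
        a = rng.random(96)[:, None]
        b = rng.random(96)[:, None]
        vals = a + b * v[None, :]
        mask = np.zeros((96, 120), bool)
        mask[:, ::4] = True
        out = sm.linear_interpolate(sm.Sinogram(vals, geom_small, mask))
        interior = slice(0, 117)  # last retained view is 116; beyond it wraps
        assert np.abs(out.values[:, interior] - vals[:, interior]).max() < 1e-9

    def test_metal_gap_matches_two_point_oracle(self, geom_small):
        rng = np.random.default_rng(6)
        vals = rng.random((96, 120))
        mask = np.ones((96, 120), bool)
        lo, hi = 40, 47  # gap of width 7 in one view
        mask[lo:hi, 3] = False
        out = sm.linear_interpolate(sm.Sinogram(vals, geom_small, mask))
        y0, y1 = vals[lo - 1, 3], vals[hi, 3]
        for k in range(lo, hi):
            t = (k - (lo - 1)) / (hi - (lo - 1))
            assert np.isclose(out.values[k, 3], y0 + t * (y1 - y0), atol=1e-12)
        untouched = mask.copy()
        assert np.array_equal(out.values[untouched], vals[untouched])

    def test_no_valid_data_rejected(self, geom_small):
        sino = sm.Sinogram(np.zeros((96, 120)), geom_small, np.zeros((96, 120), bool))
        with pytest.raises(CompletionError):
            sm.linear_interpolate(sino)


@pytest.fixture(scope="module")
def identity_model():
    cfg = NetConfig(kind="modified_unet", depth=2, base_channels=4, patch_size=32)
    model = build_modified_unet(cfg)
    for p in model.params():
        p.value[...] = 0.0
    return model


class TestUnetSynthesize:
    def test_identity_model_returns_input(self, geom_small, identity_model):
        vals = np.random.default_rng(7).random((96, 120))
        sino = sm.Sinogram(vals, geom_small)
        out = sm.unet_synthesize(sino, identity_model, invalid_mask=np.zeros_like(vals, bool))
        assert np.array_equal(out.values, vals)

    def test_measured_bins_bit_identical(self, geom_small):
        """Even a non-trivial model may only overwrite originally-missing
        entries; measured bins are restored verbatim."""
        cfg = NetConfig(kind="modified_unet", depth=2, base_channels=4, patch_size=32)
        model = build_modified_unet(cfg, seed=9)
        rng = np.random.default_rng(8)
        for p in model.params():
            p.value[...] = rng.normal(0, 0.05, p.value.shape)
        vals = rng.random((96, 120))
        invalid = rng.random((96, 120)) > 0.75
        sino = sm.Sinogram(vals, geom_small)
        out = sm.unet_synthesize(sino, model, invalid_mask=invalid)
        assert np.array_equal(out.values[~invalid], vals[~invalid])
        assert not np.array_equal(out.values[invalid], vals[invalid])

    def test_requires_initialized_sinogram(self, geom_small, identity_model):
        mask = np.ones((96, 120), bool)
        mask[0, 0] = False
        sino = sm.Sinogram(np.zeros((96, 120)), geom_small, mask)
        with pytest.raises(CompletionError):
            sm.unet_synthesize(sino, identity_model)

    def test_default_patch_size_is_64(self):
        assert NetConfig(kind="modified_unet").patch_size == 64

    def test_tile_apply_uniform_blending(self, identity_model):
        arr = np.full((96, 120), 3.25)
        out = sm.tile_apply(identity_model, arr, 32)
        assert np.allclose(out, 3.25, atol=1e-6)
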
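"""Metal segmentation, trace location, removal and reinsertion."""

import numpy as np
import pytest

import sinomar as sm
from sinomar.geometry import GeometryError
from sinomar.metal import MetalMask, MetalTrace


@pytest.fixture(scope="module")
def embedded(phantom_small, geom_small):
    wire = sm.MetalWireSpec(shape="disk", cx=8.0, cy=0.0, radius=3.0, attenuation=10.0)
    with_metal, mask = sm.embed_metal(phantom_small, wire)
    return with_metal, mask, wire, geom_small


class TestSegmentMetal:
    def test_nothing_above_threshold_gives_empty_mask(self, phantom_small):
        mask = sm.segment_metal(phantom_small, 5.0)
        assert mask.is_empty
        assert mask.metal_values.size == 0

    def test_recovers_embedded_disk_exactly(self, embedded):
        with_metal, truth, _, _ = embedded
        mask = sm.segment_metal(with_metal, 5.0)
        assert np.array_equal(mask.support, truth.support)
        assert np.array_equal(mask.metal_values, truth.metal_values)

    def test_threshold_is_inclusive(self, geom_small):
        vals = np.zeros((64, 64))
        vals[10, 10] = 5.0
        mask = sm.segment_metal(sm.ImageSlice(vals, geom_small), 5.0)
        assert mask.support[10, 10]
        assert mask.support.sum() == 1

    def test_idempotent_on_own_output(self, embedded):
        with_metal, _, _, geom = embedded
        mask = sm.segment_metal(with_metal, 5.0)
        again = sm.segment_metal(mask.as_image(geom), 5.0)
        assert np.array_equal(again.support, mask.support)


class TestComputeMetalTrace:
    def test_empty_mask_gives_empty_trace(self, geom_small):
        mask = MetalMask(np.zeros((64, 64), bool), np.empty(0))
        assert sm.compute_metal_trace(mask, geom_small).is_empty

    def test_trace_covers_every_view(self, embedded):
        _, mask, _, geom = embedded
        trace = sm.compute_metal_trace(mask, geom)
        assert trace.support.any(axis=0).all()

    def test_trace_matches_analytic_disk_band(self, embedded):
        """For a disk wire centered at (cx, cy) the trace at view theta spans
        |s - s0(theta)| < r with s0 = cx cos + cy sin, within one bin once the
        rasterized wire's physical extent (pixel half-diagonal, 0.71 px beyond
        r) is accounted for."""
        _, mask, wire, geom = embedded
        trace = sm.compute_metal_trace(mask, geom, dilate_bins=0)
        dilated = sm.compute_metal_trace(mask, geom, dilate_bins=1)
        s = geom.bin_positions
        raster = np.sqrt(0.5) * geom.pixel_size  # material extends past r
        slack = 1.0 * geom.bin_spacing + raster
        for v, theta in enumerate(geom.angles_rad):
            s0 = wire.cx * np.cos(theta) + wire.cy * np.sin(theta)
            inner = np.abs(s - s0) < wire.radius - 1.0 * geom.bin_spacing
            outer = np.abs(s - s0) > wire.radius + slack
            assert np.all(trace.support[inner, v]), f"view {v}: trace misses disk interior"
            assert not np.any(trace.support[outer, v]), f"view {v}: trace too wide"
            assert trace.support[:, v].any()
        # default 1-bin dilation widens the band by at most one bin per side
        grown = np.zeros_like(trace.support)
        grown[1:] |= trace.support[:-1]
        grown[:-1] |= trace.support[1:]
        grown |= trace.support
        assert np.array_equal(dilated.support, grown)

    def test_trace_monotone_in_mask(self, embedded, geom_small):
        _, mask, _, geom = embedded
        small = sm.compute_metal_trace(mask, geom, dilate_bins=0)
        bigger_support = np.asarray(mask.support).copy()
        bigger_support[20:26, 20:26] = True
        big_mask = MetalMask(bigger_support, np.full(int(bigger_support.sum()), 10.0))
        big = sm.compute_metal_trace(big_mask, geom, dilate_bins=0)
        assert np.all(big.support[small.support])

    def test_geometry_mismatch_rejected(self, embedded, geom_default):
        _, mask, _, _ = embedded
        with pytest.raises(GeometryError):
            sm.compute_metal_trace(mask, geom_default)


class TestRemoveReinsert:
    def test_empty_trace_leaves_sinogram_valid(self, phantom_small):
        sino = sm.forward_project(phantom_small)
        out = sm.remove_metal(sino, MetalTrace(np.zeros(sino.values.shape, bool)))
        assert out.valid_mask.all()
        assert np.array_equal(out.values, sino.values)

    def test_exact_invalid_count(self, phantom_small):
        sino = sm.forward_project(phantom_small)
        support = np.zeros(sino.values.shape, bool)
        support[40:45, 10:20] = True
        out = sm.remove_metal(sino, MetalTrace(support))
        assert (~out.valid_mask).sum() == support.sum()
        # values untouched, only flagged
        assert np.array_equal(out.values, sino.values)

    def test_completion_preserves_non_trace_bins(self, embedded):
        """remove -> interpolate leaves every non-trace bin bit-identical."""
        with_metal, mask, _, geom = embedded
        sino = sm.forward_project(with_metal)
        trace = sm.compute_metal_trace(mask, geom)
        completed = sm.linear_interpolate(sm.remove_metal(sino, trace))
        keep = ~trace.support
        assert np.array_equal(completed.values[keep], sino.values[keep])

    def test_reinsert_empty_mask_is_identity(self, phantom_small):
        mask = MetalMask(np.zeros((64, 64), bool), np.empty(0))
        out = sm.reinsert_metal(phantom_small, mask)
        assert np.array_equal(out.values, phantom_small.values)

    def test_reinsert_full_mask_replaces_everything(self, phantom_small):
        support = np.ones((64, 64), bool)
        vals = np.full(64 * 64, 7.0)
        out = sm.reinsert_metal(phantom_small, MetalMask(support, vals))
        assert np.all(out.values == 7.0)

    def test_reinsert_mixed_mask_matches_elementwise_loop(self, phantom_small, geom_small):
        rng = np.random.default_rng(2)
        support = rng.random((64, 64)) > 0.7
        vals = rng.random(int(support.sum())) * 10
        out = sm.reinsert_metal(phantom_small, MetalMask(support, vals))
        expected = phantom_small.values.copy()
        k = 0
        for i in range(64):
            for j in range(64):
                if support[i, j]:
                    expected[i, j] = vals[k]
                    k += 1
        assert np.array_equal(out.values, expected)

    def test_round_trip_reinsert_of_own_segmentation(self, embedded):
        with_metal, _, _, _ = embedded
        mask = sm.segment_metal(with_metal, 5.0)
        out = sm.reinsert_metal(with_metal, mask)
        assert np.array_equal(out.values, with_metal.values)
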
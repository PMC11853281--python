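"""Denoising cascade: stage-by-stage oracle equivalence and invariants.

Each stage is checked against an independent brute-force implementation
(tests/_oracles.py) on small randomized frames, plus the documented edge
cases: constant frames, isolated spikes, exact threshold boundaries.
"""

import numpy as np
import pytest

import _oracles as oracle
from conftest import make_diff, make_frame
from neomotion.denoise import (
    DenoiseConfig,
    clip_depth_percentiles,
    depth_difference,
    preprocess_clip,
    remove_large_differences,
    remove_small_regions,
    spatial_median_filter,
    temporal_median,
)
from neomotion.depth_io import DepthFrame


def random_depth_frames(rng, n, h, w, invalid_frac=0.15):
    """Stack of depth frames with a mix of valid/invalid pixels."""
    depths = rng.uniform(210.0, 990.0, size=(n, h, w))
    bad = rng.random((n, h, w)) < invalid_frac
    depths[bad] = rng.choice([0.0, 50.0, 1500.0], size=int(bad.sum()))
    return [DepthFrame(depths[i], timestamp=i / 30.0) for i in range(n)]


def random_diff(rng, h, w, scale=60.0, invalid_frac=0.2, sparse=0.0):
    diffs = rng.normal(0.0, scale, size=(h, w))
    if sparse:
        diffs[rng.random((h, w)) < sparse] = 0.0
    mask = rng.random((h, w)) >= invalid_frac
    return make_diff(np.where(mask, diffs, 0.0), mask)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DenoiseConfig(lower_pct=90, upper_pct=10)
        with pytest.raises(ValueError):
            DenoiseConfig(median_kernels=(4,))
        with pytest.raises(ValueError):
            DenoiseConfig(min_region_px=0)
        with pytest.raises(ValueError):
            DenoiseConfig(connectivity=6)


class TestTemporalMedian:
    def cfg(self):
        return DenoiseConfig(frames_per_median=10)

    def test_identical_frames_unchanged(self):
        base = np.full((4, 4), 500.0)
        frames = [DepthFrame(base, timestamp=i / 30.0) for i in range(60)]
        out = temporal_median(frames, self.cfg())
        assert len(out) == 2
        np.testing.assert_array_equal(out[0].depths, base)

    def test_single_outlier_rejected(self):
        frames = []
        for i in range(60):
            d = np.full((3, 3), 500.0)
            if i == 4:
                d[1, 1] = 9000.0  # out-of-range: a speckle return
            frames.append(DepthFrame(d, timestamp=i / 30.0))
        out = temporal_median(frames, self.cfg())
        assert out[0].depths[1, 1] == 500.0

    def test_matches_bruteforce_oracle(self, rng):
        frames = random_depth_frames(rng, 60, 4, 4)
        out = temporal_median(frames, self.cfg())
        for t, avg in enumerate(out):
            block = np.stack([f.depths for f in frames[t * 30 : t * 30 + 10]])
            valid = np.stack([f.valid_mask for f in frames[t * 30 : t * 30 + 10]])
            med, ok = oracle.pixelwise_median(block, valid, min_valid=5)
            np.testing.assert_array_equal(avg.valid_mask, ok)
            np.testing.assert_allclose(avg.depths[ok], med[ok])

    def test_short_clip_rejected(self):
        frames = [DepthFrame(np.full((2, 2), 500.0), timestamp=i / 30.0) for i in range(30)]
        with pytest.raises(ValueError, match="span"):
            temporal_median(frames, self.cfg())


class TestPercentileClip:
    def test_constant_frame_fully_retained(self):
        frame = make_frame(np.full((5, 5), 500.0))
        out = clip_depth_percentiles(frame)
        assert out.valid_mask.all()

    def test_default_band_bounds(self, rng):
        # 1000 in-range pixels: survivors are exactly those within [p3, p87]
        vals = rng.uniform(201.0, 300.0, size=(20, 50))
        frame = make_frame(vals)
        out = clip_depth_percentiles(frame)
        p3, p87 = np.percentile(vals, [3, 87])
        np.testing.assert_array_equal(out.valid_mask, (vals >= p3) & (vals <= p87))

    def test_matches_oracle_with_invalid_pixels(self, rng):
        for _ in range(20):
            frames = random_depth_frames(rng, 1, 10, 11)
            frame = frames[0]
            out = clip_depth_percentiles(frame)
            expect = oracle.percentile_clip(
                frame.depths, frame.valid_mask, 3, 87, (200.0, 1000.0)
            )
            np.testing.assert_array_equal(out.valid_mask, expect)

    def test_no_inrange_pixels_fully_invalidated(self):
        frame = make_frame(np.full((3, 3), 1500.0))
        out = clip_depth_percentiles(frame)
        assert not out.valid_mask.any()


class TestDepthDifference:
    def test_static_scene_zero(self):
        f = make_frame(np.full((3, 3), 500.0))
        d = depth_difference(f, f)
        assert d.valid_mask.all()
        np.testing.assert_array_equal(d.diffs, 0.0)

    def test_signed_arithmetic_and_mask_intersection(self):
        prev = make_frame([[500.0, 500.0], [0.0, 700.0]])
        curr = make_frame([[530.0, 500.0], [400.0, 0.0]])
        d = depth_difference(prev, curr)
        assert d.diffs[0, 0] == 30.0
        assert d.valid_mask.tolist() == [[True, True], [False, False]]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            depth_difference(make_frame(np.zeros((2, 2))), make_frame(np.zeros((3, 3))))


class TestSpatialMedian:
    def test_constant_frame_unchanged(self):
        d = make_diff(np.full((7, 7), 5.0))
        out = spatial_median_filter(d)
        np.testing.assert_array_equal(out.diffs, 5.0)

    def test_isolated_spike_suppressed(self):
        field = np.zeros((9, 9))
        field[4, 4] = 100.0
        out = spatial_median_filter(make_diff(field))
        assert out.diffs[4, 4] == 0.0

    @pytest.mark.parametrize("kernel", [3, 5])
    def test_matches_masked_oracle(self, rng, kernel):
        cfg = DenoiseConfig(median_kernels=(kernel,))
        for _ in range(15):
            d = random_diff(rng, 9, 9)
            out = spatial_median_filter(d, cfg)
            expect = oracle.masked_median_filter(d.diffs.copy(), d.valid_mask, kernel)
            np.testing.assert_allclose(
                out.diffs[d.valid_mask], expect[d.valid_mask], atol=1e-12
            )
            np.testing.assert_array_equal(out.valid_mask, d.valid_mask)


class TestRemoveLargeDifferences:
    def test_150mm_rule_both_signs(self):
        d = make_diff([[-10.0, 120.0, 160.0], [-170.0, 150.0, 0.0]])
        out = remove_large_differences(d)
        assert out.valid_mask.tolist() == [[True, True, False], [False, True, True]]
        assert out.diffs[0, 2] == 0.0  # invalidated values are zeroed

    def test_matches_oracle(self, rng):
        for _ in range(20):
            d = random_diff(rng, 8, 9, scale=120.0)
            out = remove_large_differences(d)
            expect = oracle.large_diff_survivors(d.diffs, d.valid_mask, 150.0)
            np.testing.assert_array_equal(out.valid_mask, expect)

    def test_idempotent(self, rng):
        d = random_diff(rng, 10, 10, scale=120.0)
        once = remove_large_differences(d)
        twice = remove_large_differences(once)
        np.testing.assert_array_equal(once.valid_mask, twice.valid_mask)
        np.testing.assert_array_equal(once.diffs, twice.diffs)


class TestRemoveSmallRegions:
    def blob(self, h, w, n_px):
        """A compact blob of exactly n_px active pixels."""
        field = np.zeros((h, w))
        coords = [(i, j) for i in range(h) for j in range(w)]
        coords.sort(key=lambda c: (c[0] - h // 2) ** 2 + (c[1] - w // 2) ** 2)
        for i, j in coords[:n_px]:
            field[i, j] = 10.0
        return field

    def test_area_boundary_at_40px(self):
        cfg = DenoiseConfig()
        kept = remove_small_regions(make_diff(self.blob(20, 20, 40)), cfg)
        assert kept.active_mask.sum() == 40
        dropped = remove_small_regions(make_diff(self.blob(20, 20, 39)), cfg)
        assert dropped.active_mask.sum() == 0

    def test_empty_frame(self):
        out = remove_small_regions(make_diff(np.zeros((5, 5))))
        assert out.active_mask.sum() == 0
        assert out.valid_mask.all()  # valid-but-inactive pixels untouched

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        cfg = DenoiseConfig(min_region_px=5, connectivity=connectivity)
        for _ in range(15):
            d = random_diff(rng, 12, 12, sparse=0.7, invalid_frac=0.1)
            out = remove_small_regions(d, cfg)
            expect = oracle.small_region_survivors(
                d.diffs, d.valid_mask, 5, connectivity
            )
            np.testing.assert_array_equal(out.valid_mask, expect)

    def test_idempotent(self, rng):
        cfg = DenoiseConfig(min_region_px=6)
        d = random_diff(rng, 12, 12, sparse=0.6)
        once = remove_small_regions(d, cfg)
        twice = remove_small_regions(once, cfg)
        np.testing.assert_array_equal(once.valid_mask, twice.valid_mask)


class TestCascade:
    def test_valid_pixels_never_increase(self, rng):
        """Each cleaning stage can only shrink the valid set."""
        d = random_diff(rng, 12, 12, scale=100.0)
        stages = [spatial_median_filter, remove_large_differences, remove_small_regions]
        current = d
        for stage in stages:
            after = stage(current)
            assert after.n_valid() <= current.n_valid()
            current = after

    def test_static_noisefree_scene_yields_no_activity(self):
        depths = np.full((16, 16), 500.0)
        frames = [DepthFrame(depths, timestamp=i / 30.0) for i in range(90)]
        diffs, _ = preprocess_clip(frames)
        assert len(diffs) == 2
        for d in diffs:
            assert d.active_mask.sum() == 0

    def test_span_arithmetic(self):
        rng = np.random.default_rng(0)
        frames = random_depth_frames(rng, 8 * 30, 6, 6, invalid_frac=0.0)
        diffs, clipped = preprocess_clip(frames)
        assert len(diffs) == 7  # 8 spans -> 7 differences
        assert len(clipped) == 8
        assert [d.second_index for d in diffs] == list(range(7))

    def test_moving_patch_survives_all_stages(self):
        """A 60 mm, ~200 px motion patch must reach the feature stage."""
        h = w = 32
        base = np.full((h, w), 500.0)
        frames = []
        for i in range(90):
            d = base.copy()
            if i >= 30:  # patch appears in the second span
                yy, xx = np.ogrid[:h, :w]
                patch = (yy - 16) ** 2 + (xx - 16) ** 2 <= 64  # ~201 px
                d[patch] -= 60.0
            frames.append(DepthFrame(d, timestamp=i / 30.0))
        diffs, _ = preprocess_clip(frames)
        active = diffs[0].active_mask
        assert active.sum() >= 150
        assert np.abs(diffs[0].diffs[active]).max() == pytest.approx(60.0)
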
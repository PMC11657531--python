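"""Background subtraction, masking, segmentation and downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainvox.core import BinaryMask, Volume
from brainvox.preprocess import (
    apply_exclusion,
    component_elongation,
    downsample,
    rolling_ball_subtract,
    segment_artifacts,
    segment_feature,
)

from conftest import random_mask, random_volume


def _brute_force_opening_2d(img, radius):
    """Independent slice oracle: erosion (min) then dilation (max) with a
    Euclidean disk, written as explicit loops."""
    h, w = img.shape
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    # 'nearest' boundary: clamp coordinates
    def clamp(src, fn):
        out = np.empty_like(src, dtype=float)
        for y in range(h):
            for x in range(w):
                vals = [
                    src[min(max(y + dy, 0), h - 1), min(max(x + dx, 0), w - 1)]
                    for dy, dx in offsets
                ]
                out[y, x] = fn(vals)
        return out
    return clamp(clamp(img, min), max)


class TestRollingBall:
    def test_constant_slice_becomes_zero(self):
        v = Volume(np.full((3, 16, 16), 7.5), 25.0, "tissue")
        out = rolling_ball_subtract(v, radius_px=4)
        np.testing.assert_allclose(out.data, 0.0)

    def test_isolated_peak_retained_in_full(self):
        data = np.zeros((1, 48, 48))
        data[0, 24, 24] = 5.0
        out = rolling_ball_subtract(Volume(data, 25.0, "tissue"), radius_px=20)
        assert out.data[0, 24, 24] == pytest.approx(5.0)

    def test_matches_brute_force_opening_on_ramp(self):
        ramp = np.add.outer(np.arange(12.0), np.arange(12.0))
        ramp[4:6, 7:9] += 3.0  # a small bump on the ramp
        v = Volume(ramp[None], 25.0, "tissue")
        out = rolling_ball_subtract(v, radius_px=3)
        expected = ramp - _brute_force_opening_2d(ramp, 3)
        np.testing.assert_allclose(out.data[0], np.clip(expected, 0, None))

    def test_bounded_by_input_and_zero(self, rng):
        v = random_volume(rng, (4, 20, 20))
        v = v.with_data(np.abs(v.data))
        out = rolling_ball_subtract(v, radius_px=3)
        assert (out.data >= 0).all()
        assert (out.data <= v.data + 1e-12).all()

    def test_nonfinite_rejected(self):
        data = np.zeros((2, 8, 8))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rolling_ball_subtract(Volume(data, 25.0, "tissue"), 3)


class TestSegmentArtifacts:
    def _tube_and_sphere(self):
        data = np.zeros((32, 32, 32))
        data[16, 16, 4:28] = 10.0  # 24-voxel tube, 1 voxel thick
        zz, yy, xx = np.ogrid[:32, :32, :32]
        sphere = (zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2 <= 9
        data[sphere] = 10.0
        return Volume(data, 25.0, "tissue"), sphere

    def test_tube_flagged_sphere_not(self):
        v, sphere = self._tube_and_sphere()
        mask = segment_artifacts(v, intensity_quantile=0.9, min_elongation=3.0)
        assert mask.data[16, 16, 16] == 1
        assert mask.data[sphere].sum() == 0

    def test_elongation_matches_svd_oracle(self):
        coords = np.argwhere(np.ones((24, 1, 1), dtype=bool))  # a straight line
        centered = coords - coords.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False) ** 2 / (len(coords) - 1)
        expected = np.sqrt((svals.max() + 1 / 12) / (svals.min() + 1 / 12))
        assert component_elongation(coords) == pytest.approx(expected)

    def test_all_zero_volume_gives_empty_mask(self):
        v = Volume(np.zeros((8, 8, 8)), 25.0, "tissue")
        assert segment_artifacts(v, 0.99, 2.0).n_voxels == 0


class TestApplyExclusion:
    def test_full_mask_zeroes_everything(self, rng):
        v = random_volume(rng)
        ones = BinaryMask(np.ones(v.data.shape, np.uint8), v.voxel_size_um, v.space)
        assert (apply_exclusion(v, ones).data == 0).all()

    def test_empty_mask_is_identity(self, rng):
        v = random_volume(rng)
        zeros = BinaryMask(np.zeros(v.data.shape, np.uint8), v.voxel_size_um, v.space)
        np.testing.assert_array_equal(apply_exclusion(v, zeros).data, v.data)

    def test_sum_identity_and_idempotence(self, rng):
        v = random_volume(rng)
        m = random_mask(rng)
        out = apply_exclusion(v, m)
        assert out.data.sum() == pytest.approx((v.data * (1 - m.data)).sum())
        np.testing.assert_array_equal(apply_exclusion(out, m).data, out.data)

    def test_zero_outside_keeps_only_masked(self, rng):
        v = random_volume(rng)
        m = random_mask(rng)
        out = apply_exclusion(v, m, mode="zero_outside")
        assert out.data.sum() == pytest.approx((v.data * m.data).sum())

    def test_grid_mismatch_rejected(self, rng):
        v = random_volume(rng)
        m = random_mask(rng, shape=(4, 4, 4))
        with pytest.raises(ValueError):
            apply_exclusion(v, m)


class TestSegmentFeature:
    def test_size_filter(self):
        data = np.zeros((10, 10, 10))
        data[1, 1, 1:4] = 1.0          # 3-voxel object
        data[5:7, 5:7, 5:8] = 1.0      # 12-voxel object (trim to 10)
        data[6, 6, 7] = 0.0
        data[5, 6, 7] = 0.0
        v = Volume(data, 25.0, "tissue")
        out = segment_feature(v, threshold=0.5, min_object_voxels=5)
        assert out.data[1, 1, 2] == 0
        assert out.data[5, 5, 5] == 1
        assert out.n_voxels == 10

    def test_threshold_above_max_gives_empty(self, rng):
        v = random_volume(rng)
        assert segment_feature(v, threshold=v.data.max() + 1).n_voxels == 0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(t1=st.floats(-1, 1), dt=st.floats(0.01, 1))
    def test_monotone_in_threshold(self, t1, dt):
        rng = np.random.default_rng(0)
        v = random_volume(rng, (6, 6, 6))
        lo = segment_feature(v, t1).astype_bool()
        hi = segment_feature(v, t1 + dt).astype_bool()
        assert (hi <= lo).all()

    def test_nonfinite_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            segment_feature(random_volume(rng), np.nan)


class TestDownsample:
    def test_factor_one_is_identity(self, rng):
        v = random_volume(rng)
        np.testing.assert_array_equal(downsample(v, 1).data, v.data)

    def test_constant_block_collapses_to_value(self):
        v = Volume(np.full((8, 8, 8), 3.25), 25.0, "tissue")
        out = downsample(v, 8)
        assert out.data.shape == (1, 1, 1)
        assert out.data[0, 0, 0] == pytest.approx(3.25)
        assert out.voxel_size_um == (200.0, 200.0, 200.0)

    def test_mean_preserved_for_exact_multiples(self, rng):
        v = random_volume(rng, (16, 8, 8))
        out = downsample(v, 4)
        assert out.data.mean() == pytest.approx(v.data.mean(), abs=1e-6)

    def test_total_intensity_preserved_through_replication(self, rng):
        v = random_volume(rng, (8, 8, 8))
        out = downsample(v, 2)
        up = np.repeat(np.repeat(np.repeat(out.data, 2, 0), 2, 1), 2, 2)
        assert up.sum() == pytest.approx(v.data.sum(), rel=1e-12)

    def test_factor_exceeding_axis_rejected(self, rng):
        with pytest.raises(ValueError):
            downsample(random_volume(rng, (4, 8, 8)), 5)
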
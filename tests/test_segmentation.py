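"""Segmentation: envelope, threshold, closing, region selection and the
variable-thickness sub-segmentation, with brute-force morphology oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microqus as mq
from microqus.segmentation import _elliptical_footprint

from conftest import tissue_extent_mask


def _make_scan(rf, fs=400e6):
    return mq.BScan(rf=np.asarray(rf, float), sampling_rate=fs, line_pitch=0.5)


class TestEnvelope:
    def test_constant_sinusoid_is_flat_zero_db(self):
        t = np.arange(4000) / 400e6
        rf = np.tile(np.sin(2 * np.pi * 48e6 * t), (3, 1))
        env = mq.compute_envelope(_make_scan(rf))
        interior = env.db[:, 100:-100]
        assert np.all(interior > -0.1)
        assert env.db.max() == 0.0

    def test_ten_times_amplitude_is_20_db(self):
        t = np.arange(4000) / 400e6
        line = np.sin(2 * np.pi * 48e6 * t)
        env = mq.compute_envelope(_make_scan(np.vstack([line, 10 * line])))
        sep = env.db[1, 100:-100] - env.db[0, 100:-100]
        assert np.allclose(sep, 20.0, atol=0.01)

    def test_all_zero_scan_rejected(self):
        with pytest.raises(ValueError, match="brightest"):
            mq.compute_envelope(_make_scan(np.zeros((2, 100))))


class TestThreshold:
    def test_literal_minus_26_db_rule(self):
        env = mq.EnvelopeImage(
            db=np.array([[0.0, -20.0, -30.0]]),
            sampling_rate=400e6, line_pitch=0.5,
            sound_speed_assumed=1540.0, depth_origin=0.0,
        )
        assert mq.threshold_mask(env, -26.0).tolist() == [[True, True, False]]

    def test_boundary_pixel_is_included(self):
        env = mq.EnvelopeImage(
            db=np.array([[0.0, -26.0]]),
            sampling_rate=400e6, line_pitch=0.5,
            sound_speed_assumed=1540.0, depth_origin=0.0,
        )
        assert mq.threshold_mask(env, -26.0).all()

    def test_nonnegative_threshold_rejected(self):
        env = mq.EnvelopeImage(
            db=np.zeros((1, 2)), sampling_rate=400e6, line_pitch=0.5,
            sound_speed_assumed=1540.0, depth_origin=0.0,
        )
        with pytest.raises(ValueError):
            mq.threshold_mask(env, 0.0)


def _brute_force_closing(mask, footprint):
    """Set-theoretic dilation-then-erosion on an effectively infinite false
    background (independent oracle for clean_mask)."""
    ry, rx = footprint.shape[0] // 2, footprint.shape[1] // 2
    offs = [(dy - ry, dx - rx) for dy in range(footprint.shape[0])
            for dx in range(footprint.shape[1]) if footprint[dy, dx]]
    pad = max(ry, rx) + 1
    m = np.pad(mask, pad)
    dil = np.zeros_like(m)
    H, W = m.shape
    for y in range(H):
        for x in range(W):
            if m[y, x]:
                for dy, dx in offs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W:
                        dil[yy, xx] = True
    ero = np.zeros_like(m)
    for y in range(H):
        for x in range(W):
            ok = True
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < H and 0 <= xx < W and dil[yy, xx]):
                    ok = False
                    break
            ero[y, x] = ok
    return ero[pad:-pad, pad:-pad]


class TestCleanMask:
    def test_matches_brute_force_oracle_on_holey_block(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        mask[5, 5] = False  # 1-pixel hole
        fp = _elliptical_footprint(1, 1)
        got = mq.clean_mask(mask, (1, 1))
        want = _brute_force_closing(mask, fp)
        assert got[5, 5]  # hole filled
        assert np.array_equal(got, want)

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((20, 20)) < 0.3
        assert np.array_equal(mq.clean_mask(mask, (0, 0)), mask)

    def test_empty_mask_stays_empty(self):
        assert not mq.clean_mask(np.zeros((5, 5), bool)).any()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_closing_extensive_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((18, 25)) < rng.uniform(0.05, 0.6)
        closed = mq.clean_mask(mask)
        assert np.all(closed | mask == closed)  # extensivity: output superset
        assert np.array_equal(mq.clean_mask(closed), closed)  # idempotence


def _brute_force_components(mask):
    """Flood-fill labelling with 8-connectivity (oracle)."""
    labels = np.zeros(mask.shape, int)
    current = 0
    for y0 in range(mask.shape[0]):
        for x0 in range(mask.shape[1]):
            if mask[y0, x0] and labels[y0, x0] == 0:
                current += 1
                stack = [(y0, x0)]
                while stack:
                    y, x = stack.pop()
                    if labels[y, x] or not mask[y, x]:
                        continue
                    labels[y, x] = current
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]:
                                if mask[yy, xx] and labels[yy, xx] == 0:
                                    stack.append((yy, xx))
    return labels, current


class TestSelectLargestRegion:
    GEOM = dict(sampling_rate=400e6, line_pitch=0.5, sound_speed_assumed=1540.0)

    def test_two_components_larger_kept(self):
        mask = np.zeros((10, 30), bool)
        mask[1:6, 2:12] = True  # 50 px
        mask[7:10, 20:30] = True  # 30 px
        roi = mq.select_largest_region(mask, **self.GEOM)
        assert roi.region_count_before_selection == 2
        assert roi.mask.sum() == 50
        labels, n = _brute_force_components(mask)
        sizes = np.bincount(labels.ravel())[1:]
        assert n == 2 and roi.mask.sum() == sizes.max()

    def test_agrees_with_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            mask = rng.random((12, 16)) < 0.35
            if not mask.any():
                continue
            roi = mq.select_largest_region(mask, **self.GEOM)
            labels, n = _brute_force_components(mask)
            assert roi.region_count_before_selection == n
            assert roi.mask.sum() == np.bincount(labels.ravel())[1:].max()

    def test_depth_bookkeeping(self):
        mask = np.zeros((3, 100), bool)
        mask[:, 40:61] = True
        roi = mq.select_largest_region(mask, **self.GEOM)
        dz = 1540.0 / (2 * 400e6) * 1e3
        assert roi.d1 == pytest.approx(40 * dz)
        assert roi.d2 == pytest.approx(60 * dz)
        assert np.allclose(roi.per_line_depths[:, 0], roi.d1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mq.select_largest_region(np.zeros((4, 4), bool), **self.GEOM)


class TestApplyMask:
    def _roi(self, mask):
        return mq.select_largest_region(
            mask, sampling_rate=400e6, line_pitch=0.5, sound_speed_assumed=1540.0
        )

    def test_all_true_identity_and_idempotence(self):
        rng = np.random.default_rng(2)
        scan = _make_scan(rng.normal(size=(4, 50)))
        roi = self._roi(np.ones((4, 50), bool))
        seg = mq.apply_mask(scan, roi)
        assert np.array_equal(seg.rf_masked, scan.rf)
        again = mq.apply_mask(_make_scan(seg.rf_masked), roi)
        assert np.array_equal(again.rf_masked, seg.rf_masked)

    def test_single_pixel_mask(self):
        scan = _make_scan(np.ones((3, 10)))
        mask = np.zeros((3, 10), bool)
        mask[1, 4] = True
        seg = mq.apply_mask(scan, self._roi(mask))
        assert np.count_nonzero(seg.rf_masked) == 1

    def test_shape_mismatch_rejected(self):
        scan = _make_scan(np.ones((3, 10)))
        with pytest.raises(ValueError, match="shape"):
            mq.apply_mask(scan, self._roi(np.ones((2, 10), bool)))


class TestSegmentRoi:
    def test_recovers_bright_band_with_high_iou(self, default_scan_set):
        seg = mq.segment_roi(default_scan_set.sample_scan)
        truth = tissue_extent_mask(default_scan_set, n_layers=1)
        inter = (truth & seg.mask.mask).sum()
        union = (truth | seg.mask.mask).sum()
        assert inter / union >= 0.95

    def test_uniform_bright_image_full_roi(self):
        t = np.arange(2000) / 400e6
        rf = np.tile(np.sin(2 * np.pi * 48e6 * t), (5, 1))
        seg = mq.segment_roi(_make_scan(rf))
        assert seg.mask.mask.mean() > 0.99

    def test_deterministic(self, default_scan_set):
        a = mq.segment_roi(default_scan_set.sample_scan)
        b = mq.segment_roi(default_scan_set.sample_scan)
        assert np.array_equal(a.mask.mask, b.mask.mask)


class TestSubSegment:
    def _uniform_segmented(self):
        t = np.arange(2000) / 400e6
        rf = np.tile(np.sin(2 * np.pi * 48e6 * t), (5, 1))
        scan = _make_scan(rf)
        mask = np.zeros((5, 2000), bool)
        mask[:, 200:1240] = True  # 2 mm at 1.925 um/sample
        roi = mq.select_largest_region(
            mask, sampling_rate=400e6, line_pitch=0.5, sound_speed_assumed=1540.0
        )
        return mq.apply_mask(scan, roi)

    def test_thickness_beyond_roi_is_identity(self):
        seg = self._uniform_segmented()
        out = mq.sub_segment_by_thickness(seg, 10.0)
        assert np.array_equal(out.mask.mask, seg.mask.mask)

    def test_half_thickness_halves_sample_count(self):
        seg = self._uniform_segmented()
        full = seg.mask.mask[0].sum()
        out = mq.sub_segment_by_thickness(seg, 1.0)  # half of the 2 mm ROI
        per_line = out.mask.mask.sum(axis=1)
        assert np.all(np.abs(per_line - full / 2) <= 1)

    def test_vanishing_thickness_keeps_top_sample(self):
        seg = self._uniform_segmented()
        out = mq.sub_segment_by_thickness(seg, 1e-6)
        per_line = out.mask.mask.sum(axis=1)
        assert np.all(per_line == 1)
        assert np.all(out.mask.mask[:, 200])

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            mq.sub_segment_by_thickness(self._uniform_segmented(), 0.0)
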
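"""SNR, modified Hausdorff distance, background rectangle, sequence rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panev.core import LineSegment
from panev.metrics import (MetricsReport, UndefinedSNR, evaluate_sequence,
                           largest_background_rectangle, mhd, mhd_segments,
                           needle_mask, snr)


def brute_force_mhd(a, b):
    def directed(p, q):
        total = 0.0
        for x in p:
            total += min(float(np.hypot(x[0] - y[0], x[1] - y[1])) for y in q)
        return total / len(p)

    return max(directed(a, b), directed(b, a))


class TestMHD:
    def test_identity_is_zero(self, rng):
        a = rng.uniform(0, 50, (20, 2))
        assert mhd(a, a) == 0.0

    def test_single_pair_euclidean(self):
        assert mhd([(0, 0)], [(3, 4)]) == pytest.approx(5.0)

    def test_hand_evaluated_asymmetric_case(self):
        # d(A,B) = (0 + 1)/2 = 0.5, d(B,A) = 0 -> max = 0.5
        assert mhd([(0, 0), (1, 0)], [(0, 0)]) == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 30, (int(rng.integers(1, 40)), 2))
            b = rng.uniform(0, 30, (int(rng.integers(1, 40)), 2))
            assert mhd(a, b) == pytest.approx(brute_force_mhd(a, b), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dx=st.floats(-50, 50), dy=st.floats(-50, 50),
           scale=st.floats(0.1, 10))
    def test_rigid_translation_invariance_and_scaling(self, dx, dy, scale):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 20, (15, 2))
        b = rng.uniform(0, 20, (12, 2))
        base = mhd(a, b)
        shift = np.array([dy, dx])
        assert mhd(a + shift, b + shift) == pytest.approx(base, rel=1e-9,
                                                          abs=1e-9)
        assert mhd(a * scale, b * scale) == pytest.approx(base * scale,
                                                          rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mhd(np.empty((0, 2)), [(1, 1)])

    def test_segments_in_mm(self):
        a = LineSegment((0, 0), (0, 10))
        b = LineSegment((10, 0), (10, 10))
        assert mhd_segments(a, b) == pytest.approx(10.0)
        assert mhd_segments(a, b, pixel_size_um=70.0) == pytest.approx(0.7)


class TestBackgroundRectangle:
    def test_empty_mask_gives_full_image(self):
        r0, c0, r1, c1 = largest_background_rectangle(np.zeros((64, 80), bool))
        assert (r0, c0, r1, c1) == (0, 0, 64, 80)

    def test_edge_needle_leaves_large_rectangle(self):
        mask = np.zeros((64, 64), bool)
        mask[:, :4] = True
        r0, c0, r1, c1 = largest_background_rectangle(mask)
        assert (r1 - r0) * (c1 - c0) >= 64 * 64 / 2

    def test_matches_brute_force_dp(self, rng):
        def brute(mask, min_size):
            free = ~mask
            h, w = mask.shape
            best = 0
            pref = np.zeros((h + 1, w + 1), dtype=int)
            pref[1:, 1:] = np.cumsum(np.cumsum(free, 0), 1)
            for r0 in range(h):
                for r1 in range(r0 + min_size, h + 1):
                    for c0 in range(w):
                        for c1 in range(c0 + min_size, w + 1):
                            area = (r1 - r0) * (c1 - c0)
                            count = (pref[r1, c1] - pref[r0, c1]
                                     - pref[r1, c0] + pref[r0, c0])
                            if count == area:
                                best = max(best, area)
            return best

        for _ in range(5):
            mask = rng.uniform(size=(18, 18)) > 0.8
            expected = brute(mask, 3)
            if expected == 0:
                with pytest.raises(ValueError):
                    largest_background_rectangle(mask, min_size=3)
                continue
            r0, c0, r1, c1 = largest_background_rectangle(mask, min_size=3)
            assert not mask[r0:r1, c0:c1].any()
            assert (r1 - r0) * (c1 - c0) == expected

    def test_no_admissible_rectangle_raises(self):
        mask = np.ones((64, 64), bool)
        mask[::8] = False  # free rows too thin for a 32x32 block
        with pytest.raises(ValueError):
            largest_background_rectangle(mask)


class TestSNR:
    def test_known_moments_construction(self):
        rng = np.random.default_rng(5)
        img = rng.standard_normal((128, 128))
        seg = LineSegment((5, 5), (45, 45))
        pts = np.arange(5, 46)
        img[pts, pts] = 10.0
        value = snr(img, seg, margin=10)
        assert value == pytest.approx(10.0, abs=0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        img = np.abs(rng.standard_normal((128, 128)))
        seg = LineSegment((10, 10), (60, 60))
        assert snr(2 * img, seg) == pytest.approx(snr(img, seg), rel=1e-12)

    def test_constant_background_is_undefined(self):
        img = np.zeros((128, 128))
        seg = LineSegment((5, 5), (40, 40))
        img[5:41, 5:41][np.eye(36, dtype=bool)] = 1.0
        with pytest.raises(UndefinedSNR):
            snr(img, seg, margin=10)

    def test_segment_outside_image_rejected(self):
        with pytest.raises(ValueError):
            snr(np.zeros((32, 32)), LineSegment((0, 0), (40, 40)))

    def test_needle_mask_margin(self):
        seg = LineSegment((10, 10), (10, 30))
        mask = needle_mask((64, 64), seg, margin=5)
        assert mask[10, 20] and mask[15, 20] and not mask[16, 20]


class TestSequenceEvaluation:
    def _labels_and_detections(self):
        seg = LineSegment((10.0, 10.0), (60.0, 60.0))
        labels, detections = [], []
        for i in range(128):
            if i < 92:
                labels.append((True, seg))
                detections.append(seg)  # perfect detection
            else:
                labels.append((False, None))
                detections.append(seg if i == 100 else None)  # one spurious
        return labels, detections

    def test_table_style_counts(self):
        labels, detections = self._labels_and_detections()
        rep = evaluate_sequence(range(128), labels,
                                lambda i: detections[i], mhd_threshold=10)
        assert rep.frames_with_needle == 92
        assert rep.frames_without_needle == 36
        assert rep.true_positives == 92 and rep.missed == 0
        assert rep.false_positives == 1
        assert rep.tp_rate_pct == pytest.approx(100.0)
        assert rep.fp_rate_pct == pytest.approx(100 / 36)  # 2.8%

    def test_all_frames_denominator_option(self):
        labels, detections = self._labels_and_detections()
        rep = evaluate_sequence(range(128), labels, lambda i: detections[i],
                                fp_denominator="all")
        assert rep.fp_rate_pct == pytest.approx(100 / 128)

    def test_oracle_and_null_detectors(self):
        seg = LineSegment((0.0, 0.0), (10.0, 10.0))
        labels = [(True, seg)] * 5 + [(False, None)] * 3
        oracle = evaluate_sequence(range(8), labels,
                                   lambda i: seg if i < 5 else None)
        assert oracle.tp_rate_pct == 100.0 and oracle.fp_rate_pct == 0.0
        null = evaluate_sequence(range(8), labels, lambda i: None)
        assert null.tp_rate_pct == 0.0 and null.fp_rate_pct == 0.0
        assert null.missed == 5

    def test_far_detection_counts_as_missed(self):
        seg = LineSegment((0.0, 0.0), (10.0, 10.0))
        far = LineSegment((100.0, 100.0), (120.0, 120.0))
        rep = evaluate_sequence([0], [(True, seg)], lambda i: far,
                                mhd_threshold=10)
        assert rep.true_positives == 0 and rep.missed == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_sequence([0, 1], [(False, None)], lambda i: None)

    def test_report_serialises(self):
        rep = MetricsReport(frames_with_needle=3, true_positives=3,
                            tp_rate_pct=100.0)
        payload = rep.to_json()
        assert payload["true_positive_rate_pct"] == 100.0
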
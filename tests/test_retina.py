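"""Retinal caliber summarisation and box-counting fractal dimension."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsretina.retina import (RetinalWidths, ZoneBGeometry, box_counting_fd,
                              compute_retinal_metrics, measure_ring_widths,
                              select_big_six, summarize_caliber)
from pvsretina.synthetic import generate_fractal_fixture

LOG3_OVER_LOG2 = np.log(3) / np.log(2)


class TestBigSix:
    def test_order_statistics(self):
        assert sorted(select_big_six(list(range(10, 18)))) == [12, 13, 14, 15, 16, 17]

    def test_exactly_six_is_identity(self):
        w = [3.0, 9.0, 4.0, 7.0, 5.0, 8.0]
        assert sorted(select_big_six(w)) == sorted(w)

    def test_insufficient_vessels_reported(self):
        with pytest.raises(ValueError, match="insufficient"):
            select_big_six([1, 2, 3, 4, 5])

    def test_ties_broken_by_first_occurrence(self):
        # seven widths, two tied at the cut: the earlier one wins
        w = np.array([5.0, 9.0, 5.0, 7.0, 8.0, 6.0, 10.0])
        out = select_big_six(w)
        assert sorted(out) == [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        # the kept 5.0 is the one at index 0
        assert out[0] == 5.0


class TestCaliber:
    def test_matches_hand_executed_reduction(self):
        """Six equal widths w: 6 -> three k*w*sqrt(2); 3 -> carry median,
        combine the outer pair to 2k^2 w; 2 -> k^2 w sqrt(4k^2+2)."""
        w, k = 10.0, 0.88
        want = k ** 2 * w * np.sqrt(4 * k ** 2 + 2)
        assert summarize_caliber([w] * 6, k) == pytest.approx(want, rel=1e-12)

    def test_distinct_widths_hand_reduction(self):
        k = 0.95
        ws = [10.0, 12.0, 14.0, 16.0, 18.0, 20.0]
        s1 = sorted([k * np.hypot(20, 10), k * np.hypot(18, 12), k * np.hypot(16, 14)])
        s2 = sorted([k * np.hypot(s1[2], s1[0]), s1[1]])
        want = k * np.hypot(s2[1], s2[0])
        assert summarize_caliber(ws, k) == pytest.approx(want, rel=1e-12)

    @given(st.lists(st.floats(1.0, 100.0), min_size=6, max_size=6),
           st.floats(0.5, 1.5))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_and_permutation_invariance(self, widths, k):
        base = summarize_caliber(widths, k)
        assert summarize_caliber([2 * w for w in widths], k) == pytest.approx(2 * base, rel=1e-9)
        assert summarize_caliber(widths[::-1], k) == pytest.approx(base, rel=1e-12)

    def test_monotone_in_each_width(self):
        base = [10.0, 11.0, 12.0, 13.0, 14.0, 15.0]
        v0 = summarize_caliber(base, 0.88)
        for i in range(6):
            bumped = list(base)
            bumped[i] += 2.0
            assert summarize_caliber(bumped, 0.88) >= v0

    def test_wrong_count_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            summarize_caliber([1, 2, 3, 4, 5], 0.88)
        with pytest.raises(ValueError):
            summarize_caliber([1, 2, 3, 4, 5, -1], 0.88)


class TestFractalDimension:
    @pytest.mark.parametrize("kind, expected", [
        ("line", 1.0),
        ("filled_square", 2.0),
        ("sierpinski", LOG3_OVER_LOG2),
    ])
    def test_analytic_fixtures(self, kind, expected):
        img = generate_fractal_fixture(kind, 128, depth=7)
        fd, r2 = box_counting_fd(img)
        assert fd == pytest.approx(expected, abs=0.05)
        assert r2 > 0.99

    def test_translation_and_rotation_invariance(self):
        img = generate_fractal_fixture("sierpinski", 128, depth=7)
        fd0, _ = box_counting_fd(img)
        fd_rot, _ = box_counting_fd(np.rot90(img))
        shifted = np.roll(img, (7, 11), axis=(0, 1))
        fd_shift, _ = box_counting_fd(shifted)
        assert fd_rot == pytest.approx(fd0, abs=0.02)
        assert fd_shift == pytest.approx(fd0, abs=0.1)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            box_counting_fd(np.zeros((64, 64), bool))

    def test_too_few_box_sizes_rejected(self):
        img = generate_fractal_fixture("line", 64)
        with pytest.raises(ValueError):
            box_counting_fd(img, box_sizes=[2, 4])


class TestRetinalMetrics:
    def test_avr_identity_with_default_coefficients(self):
        w = [20.0, 21.0, 22.0, 23.0, 24.0, 25.0]
        m = compute_retinal_metrics(RetinalWidths("left", w, w))
        assert m.avr == pytest.approx(m.crae / m.crve, abs=1e-15)

    def test_identical_sets_avr_below_one(self):
        w = [20.0] * 6
        m = compute_retinal_metrics(RetinalWidths("left", w, w))
        assert m.avr < 1.0  # k_a < k_v

    def test_unit_rescaling_leaves_avr_unchanged(self):
        wa = [18.0, 19.0, 20.0, 21.0, 22.0, 23.0]
        wv = [25.0, 26.0, 27.0, 28.0, 29.0, 30.0]
        m1 = compute_retinal_metrics(RetinalWidths("left", wa, wv))
        m2 = compute_retinal_metrics(RetinalWidths("left", [3 * w for w in wa],
                                                   [3 * w for w in wv]))
        assert m2.avr == pytest.approx(m1.avr, rel=1e-12)
        assert m2.crae == pytest.approx(3 * m1.crae, rel=1e-12)

    def test_eye_label_validated(self):
        with pytest.raises(ValueError):
            RetinalWidths("both", [1] * 6, [1] * 6)


class TestRingMeasurement:
    def test_measured_widths_match_rendered_truth(self, retinal_phantom):
        ph = retinal_phantom
        geo = ZoneBGeometry(ph.od_center, ph.od_diameter)
        for vessel_type, img in (("artery", ph.artery_map), ("vein", ph.vein_map)):
            truth = np.sort(ph.widths.loc[ph.widths["vessel_type"] == vessel_type,
                                          "width_px"].to_numpy())
            got = np.sort(measure_ring_widths(img, geo))
            assert len(got) == len(truth)
            np.testing.assert_allclose(got, truth, atol=1.0)

    def test_ring_outside_image_reported(self, retinal_phantom):
        geo = ZoneBGeometry((5.0, 5.0), 60.0)
        with pytest.raises(ValueError, match="outside"):
            measure_ring_widths(retinal_phantom.artery_map, geo)

    def test_phantom_crae_close_to_ground_truth_widths(self, retinal_phantom):
        ph = retinal_phantom
        geo = ZoneBGeometry(ph.od_center, ph.od_diameter)
        measured = measure_ring_widths(ph.artery_map, geo)
        truth = ph.widths.loc[ph.widths["vessel_type"] == "artery", "width_px"].tolist()
        crae_measured = summarize_caliber(select_big_six(measured), 0.88)
        crae_truth = summarize_caliber(select_big_six(truth), 0.88)
        assert crae_measured == pytest.approx(crae_truth, rel=0.05)
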
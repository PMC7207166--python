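"""Hallmark statistics: anchored percentages, dots, release speed, thresholds, SOC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icdquant import (
    WellSeries,
    anchored_inhibition,
    calr_dot_area,
    cv_translocation,
    hmgb1_release,
    make_hmgb1_tracks,
    positive_fraction,
    soc,
    soc_rank,
)
from icdquant.hallmarks import DegenerateAnchorsError


class TestAnchoredInhibition:
    def test_control_is_zero_percent(self):
        ctr = [1000.0, 1010.0, 990.0]
        assert anchored_inhibition(ctr, ctr, [200.0]) == pytest.approx(0.0)

    def test_blank_is_hundred_percent(self):
        blank = [200.0, 205.0, 195.0]
        assert anchored_inhibition(blank, [1000.0], blank) == pytest.approx(100.0)

    def test_midpoint_interpolates_linearly(self):
        assert anchored_inhibition([600.0], [1000.0], [200.0]) == pytest.approx(50.0)

    def test_degenerate_anchors_fail(self):
        with pytest.raises(DegenerateAnchorsError):
            anchored_inhibition([5.0], [100.0], [100.0])

    def test_values_outside_range_unclipped_by_default(self):
        assert anchored_inhibition([1200.0], [1000.0], [200.0]) < 0.0
        assert anchored_inhibition([1200.0], [1000.0], [200.0], clip=True) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        offset=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100.0),
    )
    def test_affine_invariance(self, offset, scale):
        """Shared offsets and positive rescalings leave the percentage unchanged."""
        v, c, b = np.array([600.0, 650.0]), np.array([1000.0]), np.array([200.0])
        base = anchored_inhibition(v, c, b)
        shifted = anchored_inhibition(v + offset, c + offset, b + offset)
        scaled = anchored_inhibition(v * scale, c * scale, b * scale)
        assert shifted == pytest.approx(base, abs=1e-6)
        assert scaled == pytest.approx(base, abs=1e-6)


class TestCalrDotArea:
    def _cyto(self, shape):
        mask = np.zeros(shape, dtype=np.int32)
        mask[5:-5, 5:-5] = 1
        return mask

    def test_flat_image_has_zero_area(self):
        img = np.full((64, 64), 50.0)
        mask = self._cyto((64, 64))
        # flat control too: no timepoint usable, assay fails outright
        with pytest.raises(ValueError):
            calr_dot_area([(img, mask)], [(img, mask)], [0.0], high_threshold=10.0)
        # with a dotted control the flat treated image scores area 0
        dotted = img.copy()
        dotted[30:33, 30:33] += 500.0
        series, auc, flags = calr_dot_area(
            [(img, mask), (img, mask)], [(dotted, mask), (dotted, mask)],
            [0.0, 1.0], high_threshold=10.0,
        )
        assert np.allclose(series.values, 0.0)

    def test_zero_control_timepoint_flagged_and_excluded(self):
        flat = np.full((64, 64), 50.0)
        dotted = flat.copy()
        dotted[30:33, 30:33] += 500.0
        mask = self._cyto((64, 64))
        series, auc, flags = calr_dot_area(
            [(dotted, mask)] * 3,
            [(flat, mask), (dotted, mask), (dotted, mask)],
            [0.0, 1.0, 2.0],
            high_threshold=10.0,
        )
        assert flags == [0]
        np.testing.assert_array_equal(series.timepoints, [1.0, 2.0])

    def test_treated_equals_control_gives_unit_series_and_span_auc(self):
        rng = np.random.default_rng(0)
        imgs = [np.full((64, 64), 50.0) for _ in range(4)]
        for img in imgs:
            img[20:24, 20:24] += 800.0
        mask = self._cyto((64, 64))
        t = [0.0, 1.0, 2.0, 3.0]
        pairs = [(img, mask) for img in imgs]
        series, auc, flags = calr_dot_area(pairs, pairs, t, high_threshold=100.0)
        np.testing.assert_allclose(series.values, 1.0)
        assert auc.value == pytest.approx(t[-1] - t[0])
        assert flags == []

    def test_planted_disks_recovered_within_20_percent(self):
        # 5 disks of radius 3 px on a flat background inside the mask
        img = np.full((128, 128), 50.0)
        centers = [(20, 20), (20, 60), (60, 20), (60, 60), (90, 90)]
        yy, xx = np.mgrid[:128, :128]
        for cy, cx in centers:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 9] += 1000.0
        mask = self._cyto((128, 128))
        ctrl = np.full((128, 128), 50.0)
        ctrl[100:102, 10:12] += 1000.0  # small nonzero control area
        series, auc, flags = calr_dot_area(
            [(img, mask)], [(ctrl, mask)], [0.0], tophat_radius=5, high_threshold=500.0
        )
        expected = 5 * np.pi * 9
        recovered = series.values[0] * 4  # control area = 4 px
        assert recovered == pytest.approx(expected, rel=0.2)


class TestHmgb1Release:
    def test_constant_track_has_zero_speed(self):
        tracks = [WellSeries("a", np.arange(5.0), np.full(5, 80.0))]
        result, normalized, dropped = hmgb1_release(tracks)
        assert result.value == pytest.approx(0.0)
        assert dropped == 0

    def test_worked_example_normalization_and_speed(self):
        tracks = [WellSeries("a", np.arange(4.0), np.array([100.0, 90.0, 80.0, 70.0]))]
        result, normalized, _ = hmgb1_release(tracks)
        np.testing.assert_allclose(normalized[0].values, [1.0, 0.9, 0.8, 0.7])
        assert result.value == pytest.approx(-0.1)

    def test_synthetic_decay_matches_closed_form(self):
        tracks, _ = make_hmgb1_tracks(30, 12, 0.1, noise_sd=0.0, seed=6)
        result, _, _ = hmgb1_release(tracks)
        # normalized track: 0.9^t; mean interval diff telescopes to
        # (0.9^(n-1) - 1)/(n-1)
        expected = (0.9 ** 11 - 1.0) / 11
        assert result.value == pytest.approx(expected, abs=1e-9)

    def test_telescoping_oracle_on_random_tracks(self, rng):
        values = rng.uniform(10, 1000, size=(20, 15))
        tracks = [WellSeries(f"c{i}", np.arange(15.0), v) for i, v in enumerate(values)]
        _, normalized, _ = hmgb1_release(tracks)
        for t in normalized:
            mean_diff = np.diff(t.values).mean()
            telescoped = (t.values[-1] - t.values[0]) / (len(t) - 1)
            assert mean_diff == pytest.approx(telescoped, abs=1e-12)

    def test_nonpositive_first_value_dropped_and_counted(self):
        good = WellSeries("g", np.arange(3.0), np.array([10.0, 9.0, 8.0]))
        bad = WellSeries("b", np.arange(3.0), np.array([0.0, 5.0, 4.0]))
        result, normalized, dropped = hmgb1_release([good, bad])
        assert dropped == 1
        assert result.n == 1


class TestPositiveFraction:
    def test_cells_from_positive_control_all_called(self, rng):
        neg = rng.normal(100, 10, 1000)
        pos = rng.normal(300, 10, 1000)
        frac, thr = positive_fraction(rng.normal(300, 10, 1000), neg, pos)
        assert frac >= 0.99
        assert 150 < thr < 250  # exhaustive-search oracle band

    def test_negative_control_as_test_scores_near_zero(self, rng):
        neg = rng.normal(100, 10, 1000)
        pos = rng.normal(300, 10, 1000)
        frac, _ = positive_fraction(neg, neg, pos)
        assert frac <= 0.01

    def test_direction_below_for_quinacrine_negative_calling(self, rng):
        stained = rng.normal(300, 10, 500)  # untreated keep their vesicles
        lost = rng.normal(100, 10, 500)
        frac, _ = positive_fraction(lost, stained, lost, direction="below")
        assert frac >= 0.99

    def test_identical_controls_fail(self, rng):
        ctrl = rng.normal(100, 10, 200)
        with pytest.raises(ValueError):
            positive_fraction(ctrl, ctrl, ctrl)

    def test_threshold_minimizes_misclassification_oracle(self, rng):
        neg = rng.normal(100, 20, 300)
        pos = rng.normal(180, 20, 300)
        _, thr = positive_fraction(pos, neg, pos)
        err_at = lambda c: np.sum(neg > c) + np.sum(pos <= c)
        grid = np.linspace(min(neg.min(), pos.min()), max(neg.max(), pos.max()), 5000)
        assert err_at(thr) == min(err_at(c) for c in grid)


class TestSoc:
    def test_identical_masks_give_one(self, rng):
        m = rng.random((40, 40)) > 0.7
        assert soc(m, m) == pytest.approx(1.0)

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5, :5] = True
        b[10:, 10:] = True
        assert soc(a, b) == 0.0

    def test_brute_force_pixel_count(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True        # 100 px
        b[5:10, 0:10] = True        # 50 px, all inside a
        b[10:15, 0:10] = True       # 50 px outside a
        # |A&B| = 50, |A|B| = 150
        assert soc(a, b) == pytest.approx(1.0 / 3.0)

    def test_symmetric(self, rng):
        a = rng.random((30, 30)) > 0.5
        b = rng.random((30, 30)) > 0.5
        assert soc(a, b) == soc(b, a)

    def test_monotone_under_translation_apart(self):
        base = np.zeros((40, 80), bool)
        base[10:30, 10:30] = True
        socs = []
        for shift in (0, 5, 10, 20, 40):
            other = np.roll(base, shift, axis=1)
            union = np.count_nonzero(base | other)
            socs.append(np.count_nonzero(base & other) / union)
        assert all(x >= y for x, y in zip(socs, socs[1:]))

    def test_both_empty_fails(self):
        empty = np.zeros((8, 8), bool)
        with pytest.raises(ValueError):
            soc(empty, empty)

    def test_otsu_binarization_on_intensity_images(self, rng):
        img = np.full((50, 50), 10.0)
        img[10:20, 10:20] = 200.0
        assert soc(img, img) == pytest.approx(1.0)


class TestSocRank:
    def test_control_is_zero_and_argmin_is_hundred(self):
        ranked = soc_rank({"ctr": 0.8, "w1": 0.5, "w2": 0.2}, "ctr")
        assert ranked["ctr"] == pytest.approx(0.0)
        assert ranked["w2"] == pytest.approx(100.0)
        assert ranked["w1"] == pytest.approx(50.0)

    def test_degenerate_when_control_is_minimum(self):
        with pytest.raises(ValueError):
            soc_rank({"ctr": 0.2, "w1": 0.5}, "ctr")

    def test_missing_control_fails(self):
        with pytest.raises(KeyError):
            soc_rank({"w1": 0.5, "w2": 0.3}, "ctr")


class TestCvTranslocation:
    def test_uniform_cytoplasm_gives_zero(self):
        cells = pd.DataFrame({"cyto_cv_signal": [0.0, 0.0, 0.0]})
        assert cv_translocation(cells).value == pytest.approx(0.0)

    def test_planted_rim_redistribution_gives_unit_cv(self):
        # half pixels 0, half 200 -> sd/mean = 100/100 = 1 per cell
        cells = pd.DataFrame({"cyto_cv_signal": [1.0, 1.0]})
        assert cv_translocation(cells).value == pytest.approx(1.0)

    def test_scale_invariance_of_cv(self):
        from icdquant import FieldImage, measure_cells

        nuclei = np.zeros((30, 30), dtype=np.int32)
        nuclei[5:15, 5:15] = 1
        cyto = np.zeros_like(nuclei)
        cyto[18:28, 5:15] = 1
        img = np.zeros((30, 30))
        img[18:23, 5:15] = 200.0
        for scale in (1.0, 3.5, 100.0):
            field = FieldImage(channels={"signal": img * scale})
            cells = measure_cells(field, nuclei, cyto)
            assert cells.loc[0, "cyto_cv_signal"] == pytest.approx(1.0)

    def test_no_cells_fails(self):
        with pytest.raises(ValueError):
            cv_translocation(pd.DataFrame({"cyto_cv_signal": [np.nan]}))
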
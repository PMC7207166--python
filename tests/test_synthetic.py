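"""Generators must be deterministic and expose usable planted truth."""

import numpy as np
import pytest
from scipy import stats

from icdquant import (
    ChannelSpec,
    OvercrowdedFieldError,
    SyntheticCurveSpec,
    SyntheticFieldSpec,
    ks_enrichment,
    make_compound_table,
    make_dose_response,
    make_field,
    make_hmgb1_tracks,
    make_rush_curves,
)


class TestMakeField:
    def test_empty_field_is_blank(self):
        spec = SyntheticFieldSpec(width=64, height=64, n_cells=0, seed=0)
        field, labels, truth = make_field(spec)
        assert labels.max() == 0
        assert truth.empty
        for img in field.channels.values():
            # background + read noise only: no structure above the floor
            arr = img.astype(float)
            assert arr.std() <= 2 * 5.0
            assert abs(arr.mean() - 100.0) < 5.0

    def test_identical_seed_gives_identical_pixels(self):
        spec = SyntheticFieldSpec(width=256, height=256, n_cells=10, seed=1)
        f1, l1, t1 = make_field(spec)
        f2, l2, t2 = make_field(spec)
        for role in f1.channels:
            np.testing.assert_array_equal(f1.channels[role], f2.channels[role])
        np.testing.assert_array_equal(l1, l2)
        assert t1.equals(t2)

    def test_truth_mean_reflects_planted_inhibition(self):
        # background 0 so the truth-table mean is the attenuated level alone
        spec = SyntheticFieldSpec(
            width=384, height=384, n_cells=12,
            channels=(
                ChannelSpec("dna", background=100, per_cell_level=2000, noise_sd=0),
                ChannelSpec("signal", background=0, per_cell_level=1000, noise_sd=0),
            ),
            planted_inhibition=0.5, seed=3,
        )
        _, labels, truth = make_field(spec)
        # oracle: average the rendered signal channel over each truth mask
        assert truth["signal_planted_level"].unique() == pytest.approx([500.0])
        # edge blur loses a little edge intensity but the interior holds the level
        assert truth["signal_mean_true"].mean() == pytest.approx(500.0, rel=0.05)

    def test_truth_mean_matches_pixel_average_oracle(self, small_field):
        spec, field, labels, truth = small_field
        noise_free = SyntheticFieldSpec(
            **{**spec.__dict__,
               "channels": tuple(
                   ChannelSpec(c.role, c.background, c.per_cell_level, 0.0)
                   for c in spec.channels
               )}
        )
        f0, l0, t0 = make_field(noise_free)
        for _, row in t0.iterrows():
            mask = l0 == row["cell_id"]
            assert f0.channel("signal")[mask].mean() == pytest.approx(
                row["signal_mean_true"], abs=0.5
            )  # uint16 rounding only

    def test_overcrowded_field_raises(self):
        spec = SyntheticFieldSpec(width=64, height=64, n_cells=50, seed=0)
        with pytest.raises(OvercrowdedFieldError):
            make_field(spec)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cells": -1},
            {"planted_inhibition": 1.5},
            {"nucleus_radius_px": (-1.0, 1.0)},
            {"planted_dots": (3, -1.0, 10.0)},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticFieldSpec(**kwargs)


class TestHmgb1Tracks:
    def test_zero_decay_gives_constant_tracks(self):
        tracks, _ = make_hmgb1_tracks(5, 10, 0.0, noise_sd=0.0, seed=0)
        for t in tracks:
            assert np.ptp(t.values) == 0.0

    def test_noiseless_decay_closed_form(self):
        tracks, truth = make_hmgb1_tracks(3, 8, 0.1, noise_sd=0.0, seed=4)
        for track, (_, row) in zip(tracks, truth.iterrows()):
            expected = row["initial_intensity"] * 0.9 ** np.arange(8)
            np.testing.assert_allclose(track.values, expected, rtol=1e-12)

    def test_reproducible(self):
        a, _ = make_hmgb1_tracks(4, 6, 0.2, noise_sd=5.0, seed=9)
        b, _ = make_hmgb1_tracks(4, 6, 0.2, noise_sd=5.0, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.values, tb.values)

    @pytest.mark.parametrize("decay", [-0.1, 1.1])
    def test_decay_outside_unit_interval_rejected(self, decay):
        with pytest.raises(ValueError):
            make_hmgb1_tracks(2, 5, decay)

    def test_needs_two_timepoints(self):
        with pytest.raises(ValueError):
            make_hmgb1_tracks(2, 1, 0.1)


class TestRushCurves:
    def test_full_irreversible_inhibition_collapses_to_controls(self):
        spec = SyntheticCurveSpec(planted_inhibition=1.0, planted_reversibility=1.0,
                                  noise_sd=0.0)
        rush, _ = make_rush_curves(spec)
        np.testing.assert_allclose(rush.continuous.values, rush.biotin_ctrl.values)
        np.testing.assert_allclose(rush.discontinuous.values, rush.avidin_ctrl.values)

    def test_zero_reversibility_makes_discontinuous_track_continuous(self):
        spec = SyntheticCurveSpec(planted_inhibition=1.0, planted_reversibility=0.0,
                                  noise_sd=0.0)
        rush, _ = make_rush_curves(spec)
        np.testing.assert_allclose(rush.discontinuous.values, rush.continuous.values)

    def test_half_inhibition_halves_slope(self):
        spec = SyntheticCurveSpec(planted_inhibition=0.5, noise_sd=0.0)
        rush, _ = make_rush_curves(spec)
        slope_av = np.polyfit(rush.timepoints, rush.avidin_ctrl.values, 1)[0]
        slope_cont = np.polyfit(rush.timepoints, rush.continuous.values, 1)[0]
        assert slope_cont == pytest.approx(slope_av / 2.0)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCurveSpec(timepoints=(0.0, 1.0, 3.0))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCurveSpec(timepoints=(0.0, 1.0))


class TestDoseResponse:
    def test_noiseless_counts_on_curve(self):
        b, c, d, e = 1.0, 0.0, 1.0, 1.0
        doses = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        plate, true_ic60 = make_dose_response((b, c, d, e), doses, 100, 0.0)
        expected = 100 * (c + (d - c) / (1 + doses / e))
        np.testing.assert_allclose(plate["healthy"].to_numpy(), expected, rtol=1e-12)

    def test_unit_logistic_true_ic60_is_1_5(self):
        # solve 1/(1+x) = 0.4 -> x = 1.5
        _, true_ic60 = make_dose_response((1.0, 0.0, 1.0, 1.0), [0.1, 1.0, 10.0], 100, 0.0)
        assert true_ic60 == pytest.approx(1.5)

    def test_reproducible(self):
        a, _ = make_dose_response((1.2, 0.05, 0.95, 2.0), [0.1, 1, 10], 500, 0.1, seed=5)
        b, _ = make_dose_response((1.2, 0.05, 0.95, 2.0), [0.1, 1, 10], 500, 0.1, seed=5)
        assert a.equals(b)

    def test_nonpositive_inflection_rejected(self):
        with pytest.raises(ValueError):
            make_dose_response((1.0, 0.0, 1.0, -2.0), [0.1, 1.0], 100, 0.0)

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ValueError):
            make_dose_response((1.0, 0.0, 1.0, 1.0), [1.0, 0.1], 100, 0.0)


class TestCompoundTable:
    def test_zero_shift_keeps_class_on_population_distribution(self):
        table = make_compound_table(3000, 100, planted_shift=0.0, seed=7)
        annotated = table[table["annotations"] != ""]["icd_score"]
        rest = table[table["annotations"] == ""]["icd_score"]
        assert stats.ks_2samp(annotated, rest).pvalue > 0.01

    def test_unannotated_table_is_valid_but_enrichment_refuses(self):
        table = make_compound_table(100, 0, seed=0)
        assert (table["annotations"] == "").all()
        with pytest.raises(ValueError):
            ks_enrichment(table, "transcription inhibitor")

    def test_annotated_count_bounds(self):
        with pytest.raises(ValueError):
            make_compound_table(10, 11)
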
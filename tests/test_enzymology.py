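"""Activity units, Michaelis-Menten fitting, folds, profiles, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shellmut.enzymology import (
    ActivityMeasurement,
    KineticDataset,
    MichaelisMenten,
    StabilityRecord,
    degradation_percent,
    fit_michaelis_menten,
    fold_change,
    relative_profile,
    residual_activity,
    specific_activity,
    stability_deltas,
)
from shellmut.synthdata import KineticSimSpec, generate_kinetics


class TestSpecificActivity:
    def test_beer_lambert_hand_calculation(self):
        # dA 0.38 over 3 min, 1 mL, 1 cm, eps 38000 -> 3.333e-3 U/g
        m = ActivityMeasurement(delta_absorbance=0.38, time=3.0, enzyme_mass=1.0)
        assert specific_activity(m) == pytest.approx(0.38 / 3 / 38000 * 1e3, rel=1e-12)
        assert specific_activity(m) == pytest.approx(3.333e-3, rel=1e-3)

    def test_zero_absorbance_gives_zero(self):
        m = ActivityMeasurement(delta_absorbance=0.0, time=3.0, enzyme_mass=1.0)
        assert specific_activity(m) == 0.0

    @given(
        da=st.floats(0.01, 2.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_absorbance_dilution_and_mass(self, da, scale):
        base = ActivityMeasurement(delta_absorbance=da, time=2.0, enzyme_mass=0.5)
        ref = specific_activity(base)
        assert specific_activity(
            ActivityMeasurement(da * scale, 2.0, 0.5)
        ) == pytest.approx(ref * scale, rel=1e-9)
        assert specific_activity(
            ActivityMeasurement(da, 2.0, 0.5, dilution_factor=scale)
        ) == pytest.approx(ref * scale, rel=1e-9)
        assert specific_activity(
            ActivityMeasurement(da, 2.0, 0.5 * scale)
        ) == pytest.approx(ref / scale, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            specific_activity(ActivityMeasurement(0.38, 0.0, 1.0))
        with pytest.raises(ValueError):
            specific_activity(ActivityMeasurement(0.38, 3.0, -1.0))


class TestMichaelisMenten:
    def test_noiseless_recovery_to_machine_precision(self):
        data = generate_kinetics(
            KineticSimSpec(Km=0.5, kcat=40.0, noise_sigma=0.0, replicates=1, seed=0)
        )
        fit = fit_michaelis_menten(data)
        assert fit.Km == pytest.approx(0.5, rel=1e-6)
        assert fit.kcat == pytest.approx(40.0, rel=1e-6)
        assert fit.efficiency == pytest.approx(80.0, rel=1e-6)

    def test_efficiency_is_ratio_of_estimates(self):
        # Table-style check: kcat/Km must equal the direct division of the
        # fitted parameters (0.874, 6.413 -> 7.337)
        data = generate_kinetics(
            KineticSimSpec(Km=0.874, kcat=6.413, noise_sigma=0.0, replicates=1, seed=0)
        )
        fit = fit_michaelis_menten(data)
        assert fit.efficiency == pytest.approx(fit.kcat / fit.Km, rel=1e-12)
        assert fit.efficiency == pytest.approx(6.413 / 0.874, rel=1e-6)
        assert fit.efficiency == pytest.approx(7.337, abs=1e-3)

    def test_replicate_rates_at_duplicate_levels_accepted(self):
        data = generate_kinetics(
            KineticSimSpec(Km=1.0, kcat=10.0, noise_sigma=0.02, replicates=3, seed=1)
        )
        assert np.unique(data.substrate).size == 8
        fit = fit_michaelis_menten(data)
        assert fit.Km > 0 and fit.kcat > 0

    def test_standard_errors_positive_under_noise(self):
        data = generate_kinetics(
            KineticSimSpec(Km=1.0, kcat=10.0, noise_sigma=0.05, seed=2)
        )
        fit = fit_michaelis_menten(data)
        assert fit.Km_se > 0 and fit.kcat_se > 0 and fit.efficiency_se > 0

    def test_replicate_ratio_mean_matches_pooled_ratio_when_noiseless(self):
        data = generate_kinetics(
            KineticSimSpec(Km=0.874, kcat=6.413, noise_sigma=0.0, replicates=3, seed=0)
        )
        fit = fit_michaelis_menten(data, replicate_efficiency=True)
        assert fit.efficiency_replicate_mean == pytest.approx(fit.efficiency, rel=1e-9)

    def test_replicate_ratio_mean_differs_from_pooled_under_noise(self):
        data = generate_kinetics(
            KineticSimSpec(Km=0.874, kcat=6.413, noise_sigma=0.1, replicates=3, seed=4)
        )
        fit = fit_michaelis_menten(data, replicate_efficiency=True)
        assert fit.efficiency_replicate_mean is not None
        assert fit.efficiency_replicate_mean != fit.efficiency
        # both estimate the same quantity
        assert fit.efficiency_replicate_mean == pytest.approx(fit.efficiency, rel=0.25)

    def test_unbalanced_replicates_skip_ratio_mean(self):
        data = KineticDataset(
            substrate=[0.1, 0.5, 1.0, 2.0, 2.0],
            rates=[1.0, 3.0, 4.0, 5.0, 5.1],
            enzyme_concentration=0.1,
        )
        fit = fit_michaelis_menten(data, replicate_efficiency=True)
        assert fit.efficiency_replicate_mean is None

    def test_summary_reports_parameters(self):
        data = generate_kinetics(KineticSimSpec(Km=0.5, kcat=40.0, noise_sigma=0.0, seed=0))
        text = MichaelisMenten(data).fit().summary()
        assert "Km" in text and "kcat" in text

    def test_too_few_substrate_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            KineticDataset(
                substrate=[0.1, 0.5, 1.0],
                rates=[1.0, 2.0, 3.0],
                enzyme_concentration=0.1,
            )

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticDataset(
                substrate=[0.1, 0.5, 1.0, 2.0],
                rates=[1.0, -2.0, 3.0, 4.0],
                enzyme_concentration=0.1,
            )


class TestFoldChange:
    @pytest.mark.parametrize(
        "mut,wt,expected",
        [
            (811.38, 255.95, 3.17),   # specific activity, third-shell single
            (39.786, 7.424, 5.36),    # efficiency, single mutant
            (78.580, 7.424, 10.58),   # efficiency, double mutant
            (100.0, 100.0, 1.00),
        ],
    )
    def test_published_table_ratios(self, mut, wt, expected):
        assert round(fold_change(mut, wt), 2) == expected

    @given(a=st.floats(0.01, 1e6), b=st.floats(0.01, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_folds_multiply_to_one(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestRelativeProfile:
    def test_direct_normalisation(self):
        prof = relative_profile([30, 40, 50, 60], [10, 20, 40, 30])
        assert np.allclose(prof.relative, [25, 50, 100, 75])
        assert prof.optimum == 50

    def test_maximum_is_exactly_100(self):
        prof = relative_profile([1, 2], [3.7, 9.1])
        assert prof.relative.max() == 100.0

    def test_optimum_shift_between_two_profiles(self):
        # printed optima 55 vs 40 degrees C -> 15 degree shift
        temps = [30, 35, 40, 45, 50, 55, 60]
        wt = relative_profile(temps, [40, 70, 100, 90, 75, 60, 45])
        mut = relative_profile(temps, [20, 35, 50, 65, 85, 100, 90])
        assert mut.optimum - wt.optimum == 15.0

    @given(scale=st.floats(0.001, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        raw = np.array([10.0, 20.0, 40.0, 30.0])
        a = relative_profile([1, 2, 3, 4], raw)
        b = relative_profile([1, 2, 3, 4], raw * scale)
        assert np.allclose(a.relative, b.relative)
        assert a.optimum == b.optimum

    def test_tied_maximum_flagged_and_lowest_condition_wins(self, caplog):
        with caplog.at_level("WARNING"):
            prof = relative_profile([40, 50], [7.0, 7.0])
        assert prof.optimum == 40 and prof.tied_optimum

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_profile([1, 2], [0.0, 0.0])
        with pytest.raises(ValueError):
            relative_profile([1], [5.0])


class TestResidualActivity:
    def test_percent_of_reference(self):
        assert residual_activity([48.0], 100.0)[0] == 48.0

    def test_flat_series_stays_at_100(self):
        assert np.allclose(residual_activity([7.0, 7.0, 7.0], 7.0), 100.0)

    def test_monotone_decay_stays_in_unit_interval(self, rng):
        ref = 50.0
        series = ref * np.sort(rng.random(20))[::-1]
        out = residual_activity(series, ref)
        assert np.all((out >= 0) & (out <= 100))
        assert np.all(np.diff(out) <= 1e-12)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            residual_activity([10.0], 0.0)


class TestStabilityDeltas:
    RECORDS = [
        StabilityRecord("13B22", 66.07, 379.14, None),
        StabilityRecord("D511E", 69.40, 378.53, -0.39),
        StabilityRecord("I88L-D511E", 71.13, 378.73, -0.59),
    ]

    def test_published_tm_deltas(self):
        df = stability_deltas(self.RECORDS, "13B22").set_index("enzyme")
        assert df.loc["D511E", "dTm_C"] == pytest.approx(3.33)
        assert df.loc["I88L-D511E", "dTm_C"] == pytest.approx(5.06)
        assert df.loc["13B22", "dTm_C"] == 0.0

    def test_recomputed_ddg_flags_inconsistent_stored_values(self):
        # stored -0.39 J vs recomputed 378.53 - 379.14 = -0.61 J
        df = stability_deltas(self.RECORDS, "13B22").set_index("enzyme")
        assert df.loc["D511E", "ddG_recomputed_J"] == pytest.approx(-0.61)
        assert df.loc["D511E", "ddG_consistent"] == False  # noqa: E712
        assert df.loc["13B22", "ddG_consistent"] is None

    def test_consistent_stored_value_passes_flag(self):
        records = [
            StabilityRecord("WT", 60.0, 100.0, None),
            StabilityRecord("M1", 62.0, 99.0, -1.0),
        ]
        df = stability_deltas(records, "WT").set_index("enzyme")
        assert df.loc["M1", "ddG_consistent"] == True  # noqa: E712

    def test_duplicate_ids_and_missing_wt_rejected(self):
        with pytest.raises(ValueError):
            stability_deltas(self.RECORDS + [self.RECORDS[0]], "13B22")
        with pytest.raises(KeyError):
            stability_deltas(self.RECORDS, "nope")


class TestDegradationPercent:
    def test_untreated_and_fully_degraded_extremes(self):
        assert degradation_percent(5.0, 5.0) == 0.0
        assert degradation_percent(0.0, 5.0) == 100.0

    def test_partial_degradation(self):
        assert degradation_percent(0.36 * 123.4, 123.4) == pytest.approx(64.0)

    def test_treated_above_control_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert degradation_percent(6.0, 5.0) == 0.0

    def test_invalid_peak_areas_rejected(self):
        with pytest.raises(ValueError):
            degradation_percent(1.0, 0.0)
        with pytest.raises(ValueError):
            degradation_percent(-1.0, 5.0)
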
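"""Generator determinism, truth bookkeeping, and end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

from hazelpheno.curvefit import DoubleLogisticParams, FitConfig, fit_double_logistic
from hazelpheno.phenometrics import METRIC_NAMES, extract_all
from hazelpheno.preprocessing import smooth_savitzky_golay
from hazelpheno.synthetic_data import (
    SimulationConfig,
    link_table,
    pixel_metadata,
    simulate_series,
    simulate_surveys,
    true_metrics,
)

from conftest import curve_from_params


class TestConfigValidation:
    def test_degenerate_amplitude_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(amplitude_range=(-0.1, 0.5))

    def test_unordered_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(t_up_range=(110, 85))

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dropout_prob=1.5)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_pixels=3, years=(2020,), seed=7)
        s1, t1 = simulate_series(cfg)
        s2, t2 = simulate_series(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_adding_pixels_preserves_earlier_draws(self):
        small = SimulationConfig(n_pixels=2, years=(2020,), seed=7)
        big = SimulationConfig(n_pixels=4, years=(2020,), seed=7)
        s_small, _ = simulate_series(small)
        s_big, _ = simulate_series(big)
        for a, b in zip(s_small, s_big[:2]):
            pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_different_seeds_differ(self):
        s1, _ = simulate_series(SimulationConfig(n_pixels=1, years=(2020,), seed=1))
        s2, _ = simulate_series(SimulationConfig(n_pixels=1, years=(2020,), seed=2))
        assert not np.allclose(
            s1[0].frame["evi"].to_numpy(), s2[0].frame["evi"].to_numpy(), equal_nan=True
        )


class TestSampling:
    def test_composite_count_per_year(self):
        cfg = SimulationConfig(n_pixels=1, years=(2021,), dropout_prob=0.0, seed=0)
        series, _ = simulate_series(cfg)
        assert series[0].n == 46

    def test_dropout_mean_matches_binomial(self):
        """dropout 0.1 over 46 composites loses ~4.6 per year on average."""
        missing = []
        for seed in range(40):
            cfg = SimulationConfig(n_pixels=1, years=(2021,), seed=seed)
            series, _ = simulate_series(cfg)
            missing.append((series[0].frame["flag"] == "missing").sum())
        # binomial(46, 0.1): sd ~ 2, mean of 40 draws within ~3 sigma/sqrt(40)
        assert np.mean(missing) == pytest.approx(4.6, abs=1.0)

    def test_understory_bump_raises_late_winter_values(self):
        base = SimulationConfig(n_pixels=1, years=(2021,), noise_sd=0.0, dropout_prob=0.0)
        bumped = SimulationConfig(
            n_pixels=1, years=(2021,), noise_sd=0.0, dropout_prob=0.0,
            understory_bump=(0.05, 45.0, 10.0),
        )
        s0, _ = simulate_series(base)
        s1, _ = simulate_series(bumped)
        doy = s0[0].frame["date"].dt.dayofyear
        near = (doy - 45).abs() < 8
        diff = s1[0].frame["evi"] - s0[0].frame["evi"]
        assert (diff[near] > 0.02).all()
        assert diff[(doy - 45).abs() > 60].abs().max() < 1e-3


class TestTruthLoop:
    def test_truth_equals_extractor_on_noiseless_daily_curve(self):
        """The generator's dense-grid truth and the analytic extractor agree
        on the same noiseless parameters (oracle <-> implementation loop)."""
        cfg = SimulationConfig(n_pixels=3, years=(2021,), seed=5)
        _, truth = simulate_series(cfg)
        for _, row in truth.iterrows():
            p = DoubleLogisticParams(
                row["baseline"], row["amplitude"], row["t_up"], row["s_up"],
                row["t_down"], row["s_down"], row["greendown"],
            )
            impl = extract_all(curve_from_params(p)).as_dict()
            for m in METRIC_NAMES:
                assert impl[m] == pytest.approx(row[f"true_{m}"], abs=0.5), m

    def test_true_metrics_ordering(self):
        cfg = SimulationConfig(n_pixels=5, years=(2021,), seed=9)
        _, truth = simulate_series(cfg)
        assert (truth["true_trs2_sos"] <= truth["true_trs5_sos"]).all()
        assert (truth["true_greenup"] < truth["true_maturity"]).all()
        assert (truth["true_trs5_sos"] <= truth["true_der_pos"]).all()


class TestEndToEnd:
    def test_noiseless_fit_extract_recovers_trs5_within_one_day(self):
        """Fitting the clean composites recovers the 50%-amplitude date to a
        fraction of a day (smoothing is deliberately skipped: the aggressive
        composite-cadence smoother distorts steep synthetic transitions, a
        property of that stage rather than of the fit; see the methods note)."""
        cfg = SimulationConfig(
            n_pixels=3, years=(2021,), noise_sd=0.0, dropout_prob=0.0, seed=2
        )
        series, truth = simulate_series(cfg)
        for s in series:
            curve = fit_double_logistic(s, 2021)
            got = extract_all(curve).as_dict()["trs5_sos"]
            want = truth.loc[truth["pixel_id"] == s.pixel_id, "true_trs5_sos"].item()
            assert got == pytest.approx(want, abs=1.0)

    def test_smoothing_stage_adds_bounded_distortion(self):
        """The composite-cadence smoother shifts the recovered 50%-amplitude
        date by a bounded amount (its window spans ~72 days each side)."""
        errs = []
        for seed in range(6):
            cfg = SimulationConfig(
                n_pixels=1, years=(2021,), noise_sd=0.0, dropout_prob=0.0, seed=seed
            )
            series, truth = simulate_series(cfg)
            curve = fit_double_logistic(smooth_savitzky_golay(series[0]), 2021)
            got = extract_all(curve).as_dict()["trs5_sos"]
            errs.append(abs(got - truth.loc[0, "true_trs5_sos"]))
        assert np.median(errs) < 3.0

    def test_noise_degrades_trs2_monotonically(self):
        """Median |extracted - truth| for the 20%-threshold date grows with
        the noise level."""
        med = []
        for noise in (0.0, 0.03, 0.09):
            errs = []
            for seed in range(12):
                cfg = SimulationConfig(
                    n_pixels=1, years=(2021,), noise_sd=noise, dropout_prob=0.0,
                    seed=100 + seed,
                )
                series, truth = simulate_series(cfg)
                try:
                    curve = fit_double_logistic(series[0], 2021, FitConfig(seed=seed))
                except Exception:
                    continue
                got = extract_all(curve).as_dict()["trs2_sos"]
                if got is None or not curve.converged:
                    continue
                errs.append(abs(got - truth.loc[0, "true_trs2_sos"]))
            med.append(np.median(errs))
        assert med[0] <= med[1] <= med[2]
        assert med[0] < 1.0


class TestSurveys:
    def test_row_count_without_missing(self):
        cfg = SimulationConfig(n_pixels=4, years=(2020, 2021), seed=3)
        _, truth = simulate_series(cfg)
        surveys = simulate_surveys(truth, cfg)
        # 4 pixels x 2 years x 10 phases, none missing
        assert len(surveys) == 4 * 2 * 10

    def test_phases_recorded_on_survey_weekday(self):
        cfg = SimulationConfig(n_pixels=2, years=(2021,), seed=4, survey_weekday=2)
        _, truth = simulate_series(cfg)
        surveys = simulate_surveys(truth, cfg)
        assert (surveys["date"].dt.weekday == 2).all()


class TestMetadata:
    def test_coverage_in_range_and_regions_split(self):
        cfg = SimulationConfig(n_pixels=20)
        meta = pixel_metadata(cfg)
        assert meta["coverage"].between(0.35, 1.0).all()
        assert set(meta["region"]) == {"West", "East"}
        assert meta["pixel_id"].is_unique

    def test_link_table_matches_pixels(self):
        link = link_table(SimulationConfig(n_pixels=3))
        assert list(link["orchard_id"]) == ["orchard_00", "orchard_01", "orchard_02"]
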
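"""Bias, RMSD, Spearman, distribution summaries and the full matchup table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hazelpheno.comparison import (
    MetricPhasePairs,
    bias,
    compare_all,
    pair,
    rmsd,
    spearman,
    summarize,
)
from hazelpheno.ground_obs import BBCH_ORDER
from hazelpheno.phenometrics import METRIC_NAMES


def make_pairs(metric_doy, phase_doy):
    n = len(metric_doy)
    rows = pd.DataFrame(
        {
            "orchard_id": [f"o{i}" for i in range(n)],
            "year": 2021,
            "metric_doy": metric_doy,
            "phase_doy": phase_doy,
        }
    )
    return MetricPhasePairs("m", "p", rows)


class TestBiasRmsd:
    def test_bias_of_toy_differences(self):
        assert bias(make_pairs([13, 14], [10, 10])) == pytest.approx(3.5)

    def test_bias_zero_for_identical_dates(self):
        assert bias(make_pairs([50, 60], [50, 60])) == 0.0

    def test_positive_bias_means_metric_after_phase(self):
        p = make_pairs([115, 125, 135], [100, 110, 120])
        assert bias(p) == pytest.approx(15.0)

    def test_rmsd_of_toy_differences(self):
        assert rmsd(make_pairs([13, 14], [10, 10])) == pytest.approx(math.sqrt(12.5))

    def test_rmsd_zero_for_identical_dates(self):
        assert rmsd(make_pairs([50, 60], [50, 60])) == 0.0

    def test_empty_pairs_undefined(self):
        empty = make_pairs([], [])
        with pytest.raises(ValueError):
            bias(empty)
        with pytest.raises(ValueError):
            rmsd(empty)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_rmsd_dominates_bias_and_variance_identity(self, diffs):
        p = make_pairs(np.asarray(diffs) + 100.0, np.full(len(diffs), 100.0))
        b, r = bias(p), rmsd(p)
        assert r >= abs(b) - 1e-9
        assert r**2 - b**2 == pytest.approx(np.var(diffs), abs=1e-9)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        m, g = rng.uniform(50, 150, 20), rng.uniform(50, 150, 20)
        p1 = make_pairs(m, g)
        perm = rng.permutation(20)
        p2 = make_pairs(m[perm], g[perm])
        assert bias(p1) == pytest.approx(bias(p2))
        assert rmsd(p1) == pytest.approx(rmsd(p2))


class TestSpearman:
    def test_monotone_agreement_is_plus_one(self):
        r, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)

    def test_monotone_disagreement_is_minus_one(self):
        r, _ = spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert r == pytest.approx(-1.0)

    def test_tied_vector_matches_rank_then_pearson(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])  # one tie
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        r, _ = spearman(x, y)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_exact_permutation_p_for_perfect_small_sample(self):
        # n = 5 distinct values: only the 2 extreme orderings reach |r| = 1
        _, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert p == pytest.approx(2 / math.factorial(5))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        r, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_column_flagged_undefined(self):
        r, p = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 100, 12)
        y = rng.uniform(0, 100, 12)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x / 20), y**3)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestSummarize:
    def test_linear_interpolation_median(self):
        s = summarize([10, 20, 30, 40])
        assert s.p50 == pytest.approx(25.0)
        assert s.p25 == pytest.approx(17.5)
        assert s.p75 == pytest.approx(32.5)
        assert s.mean == pytest.approx(25.0)

    def test_single_value_collapses(self):
        s = summarize([42.0])
        assert s.p25 == s.p50 == s.p75 == 42.0

    def test_percentiles_ordered(self):
        rng = np.random.default_rng(4)
        s = summarize(rng.uniform(0, 365, 100))
        assert s.p25 <= s.p50 <= s.p75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


def _tables(n_orchards=3, years=(2021,), metric_val=100.0, phase_val=90.0):
    metrics = pd.DataFrame(
        [
            {"pixel_id": f"pixel_{i}", "year": y, "trs5_sos": metric_val + i}
            for i in range(n_orchards)
            for y in years
        ]
    )
    onsets = pd.DataFrame(
        [
            {"orchard_id": f"pixel_{i}", "year": y, "bbch": "10V", "onset_doy": phase_val + i}
            for i in range(n_orchards)
            for y in years
        ]
    )
    return metrics, onsets


class TestPairing:
    def test_full_join_count(self):
        metrics, onsets = _tables(3)
        assert pair(metrics, onsets, "trs5_sos", "10V").n == 3

    def test_missing_year_absent_from_pairs(self):
        metrics, onsets = _tables(3, years=(2021, 2022))
        onsets = onsets[onsets["year"] == 2021]
        p = pair(metrics, onsets, "trs5_sos", "10V")
        assert p.n == 3
        assert set(p.rows["year"]) == {2021}

    def test_link_table_resolves_ids(self):
        metrics, onsets = _tables(2)
        onsets["orchard_id"] = onsets["orchard_id"].str.replace("pixel", "orchard")
        link = pd.DataFrame(
            {"pixel_id": ["pixel_0", "pixel_1"], "orchard_id": ["orchard_0", "orchard_1"]}
        )
        assert pair(metrics, onsets, "trs5_sos", "10V", link=link).n == 2

    def test_independent_missingness_expected_join_size(self):
        """20 orchards x 4 years with 10% loss on each side independently
        leaves about 80 * 0.81 = 64.8 pairs on average."""
        sizes = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            metrics, onsets = _tables(20, years=(2019, 2020, 2021, 2022))
            metrics = metrics[rng.random(len(metrics)) > 0.1]
            onsets = onsets[rng.random(len(onsets)) > 0.1]
            sizes.append(pair(metrics, onsets, "trs5_sos", "10V").n)
        # binomial(80, 0.81): sd ~ 3.5, so the mean of 30 draws is within ~2
        assert np.mean(sizes) == pytest.approx(64.8, abs=2.5)


class TestCompareAll:
    def _full_tables(self):
        rng = np.random.default_rng(12)
        rows_m, rows_o = [], []
        for i in range(6):
            for y in (2020, 2021):
                row = {"pixel_id": f"pixel_{i}", "year": y}
                for j, m in enumerate(METRIC_NAMES):
                    row[m] = 60 + 10 * j + rng.normal(0, 3)
                rows_m.append(row)
                for j, ph in enumerate(BBCH_ORDER):
                    rows_o.append(
                        {
                            "orchard_id": f"pixel_{i}",
                            "year": y,
                            "bbch": ph,
                            "onset_doy": 50 + 10 * j + rng.normal(0, 3),
                        }
                    )
        return pd.DataFrame(rows_m), pd.DataFrame(rows_o)

    def test_all_cells_populated(self):
        metrics, onsets = self._full_tables()
        table = compare_all(metrics, onsets)
        assert len(table) == len(METRIC_NAMES) * len(BBCH_ORDER)
        assert (table["n"] == 12).all()
        assert (table["rmsd_days"] >= table["bias_days"].abs() - 1e-9).all()

    def test_coverage_stratification_partitions_n(self):
        metrics, onsets = self._full_tables()
        coverage = pd.DataFrame(
            {
                "pixel_id": [f"pixel_{i}" for i in range(6)],
                "coverage": [0.9, 0.8, 0.9, 0.5, 0.6, 0.4],
            }
        )
        table = compare_all(metrics, onsets, coverage=coverage, min_n=1)
        cell = table[(table["metric"] == "trs5_sos") & (table["phase"] == "10V")]
        n_all = cell.loc[cell["stratum"] == "all", "n"].item()
        n_hi = cell.loc[cell["stratum"] == ">=75%", "n"].item()
        n_lo = cell.loc[cell["stratum"] == "<75%", "n"].item()
        assert n_hi + n_lo == n_all

    def test_min_n_suppresses_sparse_cells(self):
        metrics, onsets = _tables(2)
        table = compare_all(metrics, onsets, min_n=3)
        assert table.empty
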
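"""Satellite-vs-ground matchup statistics.

Phenometric dates and BBCH phase-onset dates are inner-joined per
orchard-year and compared with:

* bias — mean(metric − phase), positive when the satellite metric falls
  *after* the ground phase;
* RMSD — root mean square of the same differences (overall disagreement);
* Spearman rank correlation r_s with a two-sided p-value (t-approximation
  for n >= 10, exact/sampled permutation below that, where the
  t-approximation is unreliable);
* distribution summaries (25th/50th/75th percentile and mean).

``compare_all`` assembles the full metric x phase long table, optionally
stratified by pixel coverage fraction, flagging p < 0.05 per cell
(Benjamini–Hochberg correction available but off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .ground_obs import BBCH_ORDER
from .phenometrics import METRIC_NAMES


@dataclass
class MetricPhasePairs:
    """Paired (metric date, phase date) rows for one metric x phase cell."""

    metric: str
    phase: str
    rows: pd.DataFrame  # orchard_id, year, metric_doy, phase_doy
    n_unpaired_metric: int = 0
    n_unpaired_phase: int = 0

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def differences(self) -> np.ndarray:
        return (self.rows["metric_doy"] - self.rows["phase_doy"]).to_numpy(dtype=float)


@dataclass
class ComparisonStat:
    metric: str
    phase: str
    n: int
    bias_days: float
    rmsd_days: float
    r_s: float
    p_value: float


@dataclass
class DistributionSummary:
    label: str
    p25: float
    p50: float
    p75: float
    mean: float


def pair(
    metrics: pd.DataFrame,
    onsets: pd.DataFrame,
    metric: str,
    phase: str,
    link: pd.DataFrame | None = None,
) -> MetricPhasePairs:
    """Inner join of one phenometric column with one BBCH phase's onsets.

    ``metrics`` is the per-pixel-year table (pixel_id, year, metric columns);
    ``onsets`` the phase-onset table (orchard_id, year, bbch, onset_doy);
    ``link`` maps orchard_id <-> pixel_id (identity on names when omitted).
    Rows missing either side drop out of the join and are counted.
    """
    if metric not in metrics.columns:
        raise ValueError(f"unknown metric {metric!r}")
    m = metrics[["pixel_id", "year", metric]].dropna(subset=[metric]).copy()
    if link is not None:
        m = m.merge(link, on="pixel_id", how="inner")
    else:
        m["orchard_id"] = m["pixel_id"]
    o = onsets.loc[onsets["bbch"] == phase, ["orchard_id", "year", "onset_doy"]]
    joined = m.merge(o, on=["orchard_id", "year"], how="inner")
    rows = joined.rename(columns={metric: "metric_doy", "onset_doy": "phase_doy"})[
        ["orchard_id", "year", "metric_doy", "phase_doy"]
    ].reset_index(drop=True)
    return MetricPhasePairs(
        metric=metric,
        phase=phase,
        rows=rows,
        n_unpaired_metric=len(m) - len(joined),
        n_unpaired_phase=len(o) - len(joined),
    )


def bias(pairs: MetricPhasePairs) -> float:
    """Mean(metric − phase) in days; positive = satellite later than ground."""
    if pairs.n == 0:
        raise ValueError("bias undefined for zero pairs")
    return float(np.mean(pairs.differences))


def rmsd(pairs: MetricPhasePairs) -> float:
    """Root-mean-square difference in days."""
    if pairs.n == 0:
        raise ValueError("rmsd undefined for zero pairs")
    return float(np.sqrt(np.mean(pairs.differences**2)))


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    pairs_or_x,
    y=None,
    exact_below: int = 10,
    max_exact: int = 40320,
    n_resamples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman r_s with a two-sided p-value.

    For n >= ``exact_below`` the scipy t-approximation is used; below that a
    permutation test on the rank correlation (full enumeration when n! <=
    ``max_exact``, otherwise ``n_resamples`` seeded draws).  A constant
    column gives (nan, nan).
    """
    if y is None:
        x = pairs_or_x.rows["metric_doy"].to_numpy(dtype=float)
        y = pairs_or_x.rows["phase_doy"].to_numpy(dtype=float)
    else:
        x = np.asarray(pairs_or_x, dtype=float)
        y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs n >= 3")
    r = _spearman_r(x, y)
    if math.isnan(r):
        return math.nan, math.nan
    if n >= exact_below:
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    # permutation p-value on |r|; rank once, then correlate every permuted
    # rank vector in one matrix product
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    denom = np.sqrt(np.sum(rxc**2))
    if math.factorial(n) <= max_exact:
        perm_matrix = np.array(list(permutations(ry)))
        exact = True
    else:
        rng = np.random.default_rng(seed)
        perm_matrix = np.array([rng.permutation(ry) for _ in range(n_resamples)])
        exact = False
    pc = perm_matrix - perm_matrix.mean(axis=1, keepdims=True)
    r_all = (pc @ rxc) / (denom * np.sqrt(np.sum(pc**2, axis=1)))
    count = int(np.sum(np.abs(r_all) >= abs(r) - 1e-12))
    p = count / len(r_all) if exact else (count + 1) / (len(r_all) + 1)
    return r, float(p)


def summarize(dates, label: str = "") -> DistributionSummary:
    """25th/50th/75th percentile (linear interpolation) and mean."""
    arr = np.asarray(list(dates), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize needs a nonempty collection")
    p25, p50, p75 = np.percentile(arr, [25, 50, 75])
    return DistributionSummary(label, float(p25), float(p50), float(p75), float(arr.mean()))


def _stat_row(p: MetricPhasePairs, seed: int) -> dict:
    row = {"metric": p.metric, "phase": p.phase, "n": p.n}
    row["bias_days"] = bias(p)
    row["rmsd_days"] = rmsd(p)
    if p.n >= 3:
        r, pv = spearman(p, seed=seed)
    else:
        r, pv = math.nan, math.nan
    row["r_s"], row["p_value"] = r, pv
    row["significant_05"] = bool(pv < 0.05) if not math.isnan(pv) else False
    return row


def compare_all(
    metrics: pd.DataFrame,
    onsets: pd.DataFrame,
    link: pd.DataFrame | None = None,
    metric_names=METRIC_NAMES,
    phases=BBCH_ORDER,
    min_n: int = 3,
    coverage: pd.DataFrame | None = None,
    coverage_threshold: float = 0.75,
    bh_correct: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Long table of ComparisonStat rows over every metric x phase cell.

    When ``coverage`` (pixel_id, coverage) is given, cells are additionally
    computed per stratum (coverage >= / < ``coverage_threshold``) with a
    ``stratum`` column; the unstratified table labels all rows ``all``.
    """
    strata: list[tuple[str, pd.DataFrame]] = [("all", metrics)]
    if coverage is not None:
        cov = metrics.merge(coverage[["pixel_id", "coverage"]], on="pixel_id", how="left")
        strata.append((f">={coverage_threshold:.0%}", cov[cov["coverage"] >= coverage_threshold]))
        strata.append((f"<{coverage_threshold:.0%}", cov[cov["coverage"] < coverage_threshold]))
    rows = []
    present = [m for m in metric_names if m in metrics.columns]
    for label, mtable in strata:
        for metric in present:
            for phase in phases:
                p = pair(mtable, onsets, metric, phase, link=link)
                if p.n < min_n:
                    continue
                row = _stat_row(p, seed)
                row["stratum"] = label
                rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "metric",
            "phase",
            "n",
            "bias_days",
            "rmsd_days",
            "r_s",
            "p_value",
            "significant_05",
        ],
    )
    if bh_correct and len(out):
        for label in out["stratum"].unique():
            mask = (out["stratum"] == label) & out["p_value"].notna()
            pvals = out.loc[mask, "p_value"].to_numpy()
            if pvals.size:
                out.loc[mask, "p_value_bh"] = _benjamini_hochberg(pvals)
        out["significant_05"] = out.get("p_value_bh", out["p_value"]) < 0.05
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out


__all__ = [
    "MetricPhasePairs",
    "ComparisonStat",
    "DistributionSummary",
    "pair",
    "bias",
    "rmsd",
    "spearman",
    "summarize",
    "compare_all",
]
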
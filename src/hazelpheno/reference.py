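"""Dense-grid brute-force phenometric extraction.

An independent implementation of the eight transition dates that works on
*samples of the curve only*: it takes any callable ``f(t)`` (or a dense array
of values), differentiates numerically and scans a fine grid.  It deliberately
shares no derivative code with :mod:`hazelpheno.phenometrics`, so the two
routes cross-check each other; the synthetic-data generator also uses it to
tabulate ground-truth dates from the noiseless curve.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter1d

DEFAULT_STEP = 0.01


def dense_season_geometry(f, t_lo: float, t_hi: float, step: float = DEFAULT_STEP):
    """(trough_doy, peak_doy, baseline_value, peak_value) by dense scan."""
    grid = np.arange(t_lo, t_hi + step / 2, step)
    vals = np.asarray(f(grid))
    i_peak = int(np.argmax(vals))
    before = grid < grid[i_peak]
    if not before.any():
        raise ValueError("peak at the start of the window")
    i_trough = int(np.argmin(np.where(before, vals, np.inf)))
    return (
        float(grid[i_trough]),
        float(grid[i_peak]),
        float(vals[i_trough]),
        float(vals[i_peak]),
    )


def dense_metrics(
    f,
    t_lo: float,
    t_hi: float,
    step: float = DEFAULT_STEP,
) -> dict:
    """All eight phenometrics by brute force on a ``step``-day grid.

    Derivatives and curvature are numerical (``np.gradient`` on the sampled
    values); local maxima of the curvature change rate are located by simple
    neighbour comparison.  Missing metrics are returned as None.
    """
    grid = np.arange(t_lo, t_hi + step / 2, step)
    vals = np.asarray(f(grid), dtype=float)
    i_peak = int(np.argmax(vals))
    peak_doy = float(grid[i_peak])
    before = grid < peak_doy
    if not before.any():
        raise ValueError("peak at the start of the window")
    i_trough = int(np.argmin(np.where(before, vals, np.inf)))
    trough_doy = float(grid[i_trough])
    baseline, peak_val = float(vals[i_trough]), float(vals[i_peak])
    amp = peak_val - baseline

    rising = slice(i_trough, i_peak + 1)
    g = grid[rising]
    v = vals[rising]

    out: dict = {"der_pos": peak_doy}

    # threshold metrics: first dense-grid day at/above the level
    for frac, name in ((0.2, "trs2_sos"), (0.5, "trs5_sos")):
        thr = baseline + frac * amp
        above = v >= thr
        out[name] = float(g[int(np.argmax(above))]) if above.any() else None

    d1 = np.gradient(vals, step)
    i_sos = i_trough + int(np.argmax(d1[rising]))
    out["der_sos"] = float(grid[i_sos])

    k = float(d1[i_sos])
    if k > 0:
        vstar = float(vals[i_sos])
        out["gu_ud"] = float(grid[i_sos]) + (baseline - vstar) / k
        out["gu_sd"] = float(grid[i_sos]) + (peak_val - vstar) / k
        out["gu_ud"] = max(out["gu_ud"], float(grid[0]))
        out["gu_sd"] = min(out["gu_sd"], float(grid[-1]))
    else:
        out["gu_ud"] = out["gu_sd"] = None

    d2 = np.gradient(d1, step)
    curv = d2 / (1.0 + d1**2) ** 1.5
    kprime = np.gradient(curv, step)
    kp = kprime[rising]
    # windowed (+-0.5 day) maxima are robust to float-noise ripples in the
    # near-flat winter tail; a 1-day edge margin drops artefacts of the
    # one-sided gradient stencils at the scan boundary
    w = max(int(round(0.5 / step)), 1)
    filt = maximum_filter1d(kp, size=2 * w + 1, mode="nearest")
    cand = np.flatnonzero(kp >= filt)
    cand = cand[(g[cand] > g[0] + 1.0) & (g[cand] < g[-1] - 1.0)]
    if cand.size and kp[cand].max() > 0:
        cand = cand[kp[cand] >= 1e-3 * kp[cand].max()]
    clusters = _split_clusters(g, cand, gap=1.0)
    if len(clusters) >= 2:
        out["greenup"] = float(g[int(clusters[0][0])])
        out["maturity"] = float(g[int(clusters[-1][-1])])
    else:
        out["greenup"] = out["maturity"] = None
    return out


def _split_clusters(g: np.ndarray, idx: np.ndarray, gap: float) -> list:
    """Group sorted indices into clusters separated by more than ``gap`` days."""
    if idx.size == 0:
        return []
    clusters = [[int(idx[0])]]
    for i in idx[1:]:
        if g[int(i)] - g[clusters[-1][-1]] > gap:
            clusters.append([int(i)])
        else:
            clusters[-1].append(int(i))
    return clusters


__all__ = ["dense_metrics", "dense_season_geometry", "DEFAULT_STEP"]
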
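"""Spring phenometric extraction from a fitted daily seasonal curve.

Eight transition dates, in four families:

* threshold — first day the curve reaches 20% / 50% of the annual amplitude
  above the seasonal baseline (``trs2_sos``, ``trs5_sos``);
* derivative — day of fastest increase (``der_sos``) and of the curve
  maximum (``der_pos``);
* tangent ("recovery line") — the tangent at the fastest-increase day
  intersected with the baseline and the peak line (``gu_ud``, ``gu_sd``);
* curvature change rate — first and last local maxima of K'(t) on the rising
  limb (``greenup``, ``maturity``).

All searches are restricted to the rising segment [trough, peak], bracketed
on the 1-day grid and refined on the continuous analytic curve, so returned
days are floats with sub-daily precision; writers round to whole days.
Ties (plateaus) break to the earliest day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .curvefit import (
    FittedCurve,
    SeasonGeometry,
    curvature_rate,
    curve_derivative,
    derive_season_geometry,
    evaluate_curve,
)

METRIC_NAMES = (
    "der_sos",
    "der_pos",
    "trs2_sos",
    "trs5_sos",
    "gu_ud",
    "gu_sd",
    "greenup",
    "maturity",
)


@dataclass
class PhenometricSet:
    """The eight extracted transition dates (day-of-year) for one pixel-year.

    A metric that could not be computed is ``None`` with an entry in
    ``reasons``; ``low_confidence`` lists metrics affected by grid clipping
    or a boundary season.
    """

    pixel_id: str
    year: int
    der_sos: Optional[float] = None
    der_pos: Optional[float] = None
    trs2_sos: Optional[float] = None
    trs5_sos: Optional[float] = None
    gu_ud: Optional[float] = None
    gu_sd: Optional[float] = None
    greenup: Optional[float] = None
    maturity: Optional[float] = None
    reasons: dict = None
    low_confidence: tuple = ()

    def __post_init__(self):
        if self.reasons is None:
            self.reasons = {}

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def to_row(self) -> dict:
        row = {"pixel_id": self.pixel_id, "year": self.year}
        row.update(self.as_dict())
        row["reasons"] = ";".join(f"{k}={v}" for k, v in self.reasons.items())
        return row


def _rising_grid(curve: FittedCurve, geometry: SeasonGeometry) -> np.ndarray:
    lo = float(np.ceil(geometry.trough_doy))
    hi = float(np.floor(geometry.peak_doy))
    if hi < lo:
        return np.array([geometry.trough_doy])
    return np.arange(lo, hi + 1.0)


def extract_trs(
    curve: FittedCurve, geometry: SeasonGeometry, fraction: float
) -> Optional[float]:
    """First day on the rising limb where the curve reaches
    ``baseline + fraction * amplitude``; None when there is no crossing."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    thr = geometry.baseline_value + fraction * geometry.amplitude
    p = curve.params

    def g(t):
        return evaluate_curve(p, t) - thr

    lo, hi = geometry.trough_doy, geometry.peak_doy
    if g(lo) >= 0:
        return float(lo)
    if g(hi) < 0:
        return None
    grid = np.linspace(lo, hi, max(int(hi - lo) + 1, 2))
    vals = np.asarray(evaluate_curve(p, grid)) - thr
    idx = int(np.argmax(vals >= 0))  # earliest grid day at/above threshold
    a = grid[idx - 1] if idx > 0 else lo
    b = grid[idx]
    if g(b) < 0:  # numerical corner: threshold reached between grid and peak
        a, b = grid[-1], hi
    return float(brentq(g, a, b, xtol=1e-8))


def _argmax_refined(func, grid: np.ndarray) -> float:
    vals = np.asarray(func(grid))
    i = int(np.argmax(vals))  # np.argmax takes the earliest maximal index
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(
        lambda t: -float(func(t)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    # a flat plateau can make the refined point later than the grid argmax
    return float(res.x) if -res.fun > vals[i] + 1e-15 else float(grid[i])


def extract_der(
    curve: FittedCurve, geometry: SeasonGeometry
) -> tuple[Optional[float], Optional[float]]:
    """Day of fastest increase on the rising limb and day of the curve peak."""
    grid = _rising_grid(curve, geometry)
    p = curve.params
    der_sos = _argmax_refined(lambda t: curve_derivative(p, t, 1), grid)
    return float(der_sos), float(geometry.peak_doy)


def extract_gu(
    curve: FittedCurve, geometry: SeasonGeometry
) -> tuple[Optional[float], Optional[float], dict, tuple]:
    """Tangent ("recovery") line construction.

    The line through (t*, f(t*)) with slope f'(t*), t* the fastest-increase
    day, is intersected with the baseline (upturn date) and the peak line
    (stabilisation date).  Intersections outside the daily grid are clipped
    and flagged low-confidence.
    """
    reasons: dict = {}
    low: list = []
    der_sos, _ = extract_der(curve, geometry)
    p = curve.params
    k = float(curve_derivative(p, der_sos, 1))
    if k <= 0:
        return None, None, {"gu_ud": "nonpositive_slope", "gu_sd": "nonpositive_slope"}, ()
    v = float(evaluate_curve(p, der_sos))
    gu_ud = der_sos + (geometry.baseline_value - v) / k
    gu_sd = der_sos + (geometry.peak_value - v) / k
    lo_g, hi_g = float(curve.doy_grid[0]), float(curve.doy_grid[-1])
    if gu_ud < lo_g:
        gu_ud = lo_g
        low.append("gu_ud")
    if gu_sd > hi_g:
        gu_sd = hi_g
        low.append("gu_sd")
    return float(gu_ud), float(gu_sd), reasons, tuple(low)


def extract_zhang(
    curve: FittedCurve, geometry: SeasonGeometry, step: float = 0.1
) -> tuple[Optional[float], Optional[float], dict]:
    """First and last local maxima of the curvature change rate K'(t) on the
    rising limb (onset of photosynthetic activity and leaf-area maximum)."""
    p = curve.params
    lo, hi = geometry.trough_doy, geometry.peak_doy
    grid = np.arange(lo, hi + step / 2, step)
    if grid.size < 5:
        return None, None, {"greenup": "segment_too_short", "maturity": "segment_too_short"}
    kr = np.asarray(curvature_rate(p, grid))
    interior = np.arange(1, grid.size - 1)
    is_max = (kr[interior] > kr[interior - 1]) & (kr[interior] >= kr[interior + 1])
    peaks = interior[is_max]
    # drop float-noise ripples in the flat winter tail, where K' ~ 0
    if peaks.size and kr[peaks].max() > 0:
        peaks = peaks[kr[peaks] >= 1e-3 * kr[peaks].max()]
    if peaks.size < 2:
        return None, None, {
            "greenup": "fewer_than_two_curvature_rate_maxima",
            "maturity": "fewer_than_two_curvature_rate_maxima",
        }

    def refine(i):
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        res = minimize_scalar(
            lambda t: -float(curvature_rate(p, t)), bounds=(a, b), method="bounded",
            options={"xatol": 1e-6},
        )
        return float(res.x)

    greenup = refine(int(peaks[0]))
    maturity = refine(int(peaks[-1]))
    if not greenup < maturity:
        return None, None, {"greenup": "unordered_maxima", "maturity": "unordered_maxima"}
    return greenup, maturity, {}


def extract_all(
    curve: FittedCurve, geometry: SeasonGeometry | None = None
) -> PhenometricSet:
    """Run every extractor, collecting per-metric failure reasons.

    An unconverged curve yields an all-missing set; a degenerate individual
    metric never raises.
    """
    out = PhenometricSet(pixel_id=curve.pixel_id, year=curve.year)
    if not curve.converged:
        out.reasons = {m: "unconverged_fit" for m in METRIC_NAMES}
        return out
    try:
        geom = geometry if geometry is not None else derive_season_geometry(curve)
    except ValueError as exc:
        out.reasons = {m: f"geometry_error:{exc}" for m in METRIC_NAMES}
        return out

    low: list = []
    if geom.boundary_warning:
        low.extend(METRIC_NAMES)

    out.der_sos, out.der_pos = extract_der(curve, geom)
    for frac, name in ((0.2, "trs2_sos"), (0.5, "trs5_sos")):
        val = extract_trs(curve, geom, frac)
        if val is None:
            out.reasons[name] = "no_threshold_crossing"
        else:
            setattr(out, name, val)
    gu_ud, gu_sd, gu_reasons, gu_low = extract_gu(curve, geom)
    out.gu_ud, out.gu_sd = gu_ud, gu_sd
    out.reasons.update(gu_reasons)
    low.extend(gu_low)
    out.greenup, out.maturity, z_reasons = extract_zhang(curve, geom)
    out.reasons.update(z_reasons)
    out.low_confidence = tuple(dict.fromkeys(low))
    return out


def metrics_table(sets: list[PhenometricSet], round_days: bool = True) -> pd.DataFrame:
    """One row per pixel-year with the eight metric columns.

    ``round_days`` reports whole days (the field convention for phenology
    tables); internal values keep sub-daily precision.
    """
    rows = [s.to_row() for s in sets]
    df = pd.DataFrame(
        rows, columns=["pixel_id", "year", *METRIC_NAMES, "reasons"]
    )
    if round_days:
        for m in METRIC_NAMES:
            df[m] = df[m].round(0)
    return df


__all__ = [
    "METRIC_NAMES",
    "PhenometricSet",
    "extract_trs",
    "extract_der",
    "extract_gu",
    "extract_zhang",
    "extract_all",
    "metrics_table",
]
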
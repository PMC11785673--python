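"""Raw reflectance / EVI records -> quality-filtered, smoothed composite series.

The stages mirror a standard MODIS-style vegetation-index workflow:

1. :func:`compute_evi` — Enhanced Vegetation Index from NIR/red/blue surface
   reflectance.
2. :func:`composite_mvc` — maximum-value compositing on a fixed calendar
   (periods restart every Jan 1; 46 eight-day periods per non-leap year).
3. :func:`apply_quality_filter` — expert floor rules (EVI > 0.1 year-round,
   EVI > 0.3 in the June–August window by default).
4. :func:`smooth_savitzky_golay` — Savitzky–Golay polynomial smoothing with
   gap interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_DISCARDED = "discarded"
FLAG_MISSING = "missing"


class SmoothingError(ValueError):
    """Raised when a series has too few valid points to smooth."""


@dataclass(frozen=True)
class EviCoefficients:
    """Gain / aerosol-resistance / canopy-background coefficients of the EVI."""

    gain: float = 2.5
    c1: float = 6.0
    c2: float = 7.5
    background: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gain", "c1", "c2", "background"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"EVI coefficient {name!r} must be finite")


DEFAULT_EVI_COEFFICIENTS = EviCoefficients()


@dataclass(frozen=True)
class QualityRules:
    """Expert floor rules applied to an EVI series.

    ``annual_min`` is the floor enforced year-round, ``summer_min`` the
    stricter floor inside ``summer_window`` (inclusive month-day bounds).
    """

    annual_min: float = 0.1
    summer_min: float = 0.3
    summer_window: tuple[tuple[int, int], tuple[int, int]] = ((6, 1), (8, 31))

    def __post_init__(self) -> None:
        if not self.annual_min < self.summer_min:
            raise ValueError("annual_min must be below summer_min")


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky–Golay window half-width (composite steps) and polynomial degree."""

    half_width: int = 9
    degree: int = 3

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if not self.degree < 2 * self.half_width + 1:
            raise ValueError("degree must be < window length 2*half_width+1")

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1


@dataclass
class EviTimeSeries:
    """One pixel's dated EVI values with per-entry quality flags.

    ``frame`` holds columns ``date`` (datetime64), ``evi`` (float, NaN for
    missing) and ``flag`` (one of ``ok``/``discarded``/``missing``), sorted by
    strictly increasing date.  ``cadence_days`` is the nominal step (8 for
    composites, 1 for daily).
    """

    pixel_id: str
    frame: pd.DataFrame
    cadence_days: int = 8

    def __post_init__(self) -> None:
        f = self.frame
        required = {"date", "evi", "flag"}
        if not required.issubset(f.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        f = f.copy()
        f["date"] = pd.to_datetime(f["date"])
        f = f.sort_values("date").reset_index(drop=True)
        if f["date"].duplicated().any():
            raise ValueError(f"duplicate dates in series for pixel {self.pixel_id}")
        bad = ~f["flag"].isin([FLAG_OK, FLAG_DISCARDED, FLAG_MISSING])
        if bad.any():
            raise ValueError(f"unknown flags: {sorted(f.loc[bad, 'flag'].unique())}")
        self.frame = f

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def ok_mask(self) -> np.ndarray:
        return (self.frame["flag"] == FLAG_OK).to_numpy()

    def years(self) -> list[int]:
        return sorted(self.frame["date"].dt.year.unique().tolist())

    def copy(self) -> "EviTimeSeries":
        return EviTimeSeries(self.pixel_id, self.frame.copy(), self.cadence_days)


@dataclass
class FilterReport:
    """Outcome of the expert quality filter on one series."""

    pixel_id: str
    n_total: int
    per_rule: dict[str, int] = field(default_factory=dict)
    n_discarded: int = 0

    @property
    def fraction_discarded(self) -> float:
        return self.n_discarded / self.n_total if self.n_total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "count": c} for r, c in self.per_rule.items()]
        rows.append({"rule": "total_unique", "count": self.n_discarded})
        return pd.DataFrame(rows)


ArrayLike = Union[float, np.ndarray]


def compute_evi(
    rho_nir: ArrayLike,
    rho_red: ArrayLike,
    rho_blue: ArrayLike,
    coeffs: EviCoefficients = DEFAULT_EVI_COEFFICIENTS,
    denom_tol: float = 1e-6,
) -> np.ndarray:
    """Enhanced Vegetation Index, G·(ρNIR − ρred)/(ρNIR + C1·ρred − C2·ρblue + L).

    Vectorised over inputs.  A near-zero denominator or a result outside the
    valid [−1, 1] range yields NaN (invalid sample) rather than an exception.
    """
    nir = np.asarray(rho_nir, dtype=float)
    red = np.asarray(rho_red, dtype=float)
    blue = np.asarray(rho_blue, dtype=float)
    denom = nir + coeffs.c1 * red - coeffs.c2 * blue + coeffs.background
    with np.errstate(divide="ignore", invalid="ignore"):
        evi = coeffs.gain * (nir - red) / denom
    evi = np.where(np.abs(denom) < denom_tol, np.nan, evi)
    evi = np.where(np.abs(evi) > 1.0, np.nan, evi)
    return evi if evi.ndim else float(evi)


def evi_from_reflectance_table(
    table: pd.DataFrame, coeffs: EviCoefficients = DEFAULT_EVI_COEFFICIENTS
) -> pd.DataFrame:
    """Add ``evi`` and ``flag`` columns to a reflectance table.

    Expects columns ``pixel_id``, ``date``, ``rho_nir``, ``rho_red``,
    ``rho_blue`` and optionally ``qa`` (nonzero qa marks the row missing).
    """
    out = table.copy()
    evi = compute_evi(
        out["rho_nir"].to_numpy(),
        out["rho_red"].to_numpy(),
        out["rho_blue"].to_numpy(),
        coeffs,
    )
    out["evi"] = evi
    flags = np.where(np.isnan(np.atleast_1d(evi)), FLAG_MISSING, FLAG_OK)
    if "qa" in out.columns:
        qa_bad = out["qa"].fillna(0).astype(float).to_numpy() != 0
        flags = np.where(qa_bad, FLAG_MISSING, flags)
    out["flag"] = flags
    return out


def _period_starts(year: int, period_days: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=year, month=1, day=1)
    end = pd.Timestamp(year=year + 1, month=1, day=1)
    return pd.date_range(start, end - pd.Timedelta(days=1), freq=f"{period_days}D")


def composite_mvc(series: EviTimeSeries, period_days: int = 8) -> EviTimeSeries:
    """Maximum-value composite on a calendar restarting each Jan 1.

    Each period is dated at its start; its value is the maximum EVI over
    ``ok`` entries falling inside it (periods are truncated at Dec 31, the
    MODIS convention, giving 46 periods per non-leap year for 8-day periods).
    Periods with no valid entry are emitted flagged ``missing``.
    """
    if period_days < 1:
        raise ValueError("period_days must be >= 1")
    if series.n == 0:
        return EviTimeSeries(series.pixel_id, _empty_frame(), period_days)
    f = series.frame
    rows = []
    for year in series.years():
        starts = _period_starts(year, period_days)
        year_end = pd.Timestamp(year=year + 1, month=1, day=1)
        for start in starts:
            stop = min(start + pd.Timedelta(days=period_days), year_end)
            in_period = (f["date"] >= start) & (f["date"] < stop)
            ok = in_period & (f["flag"] == FLAG_OK)
            if ok.any():
                rows.append({"date": start, "evi": f.loc[ok, "evi"].max(), "flag": FLAG_OK})
            else:
                rows.append({"date": start, "evi": np.nan, "flag": FLAG_MISSING})
    return EviTimeSeries(series.pixel_id, pd.DataFrame(rows), period_days)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({"date": pd.to_datetime([]), "evi": [], "flag": []})


def _in_summer_window(dates: pd.Series, window) -> np.ndarray:
    (m0, d0), (m1, d1) = window
    md = dates.dt.month * 100 + dates.dt.day
    return ((md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)).to_numpy()


def apply_quality_filter(
    series: EviTimeSeries, rules: QualityRules = QualityRules()
) -> tuple[EviTimeSeries, FilterReport]:
    """Flag entries below the expert floors as ``discarded``.

    An entry violating both floors is counted once in the unique total but
    appears in each rule's count.  Already missing entries are untouched.
    """
    f = series.frame.copy()
    ok = f["flag"] == FLAG_OK
    annual_bad = ok & (f["evi"] <= rules.annual_min)
    summer = _in_summer_window(f["date"], rules.summer_window)
    summer_bad = ok & summer & (f["evi"] <= rules.summer_min)
    any_bad = annual_bad | summer_bad
    f.loc[any_bad, "flag"] = FLAG_DISCARDED
    report = FilterReport(
        pixel_id=series.pixel_id,
        n_total=int(ok.sum()),
        per_rule={
            "annual_floor": int(annual_bad.sum()),
            "summer_floor": int(summer_bad.sum()),
        },
        n_discarded=int(any_bad.sum()),
    )
    if report.n_discarded:
        logger.info(
            "quality_filter pixel=%s discarded=%d/%d (annual=%d summer=%d)",
            series.pixel_id,
            report.n_discarded,
            report.n_total,
            report.per_rule["annual_floor"],
            report.per_rule["summer_floor"],
        )
    return EviTimeSeries(series.pixel_id, f, series.cadence_days), report


def _interpolate_gaps(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation over invalid entries, edges held at nearest valid."""
    idx = np.arange(values.size, dtype=float)
    return np.interp(idx, idx[valid], values[valid])


def smooth_savitzky_golay(
    series: EviTimeSeries, config: SmoothingConfig = SmoothingConfig()
) -> EviTimeSeries:
    """Savitzky–Golay smoothing of a regular composite series.

    Discarded/missing entries are linearly interpolated before filtering so
    the filter sees a regular grid, and keep their flags afterwards.  Edges
    use a least-squares polynomial fit over the terminal window, which leaves
    polynomial signals of degree <= ``config.degree`` exactly unchanged all
    the way to the boundary (January/December composites matter for the
    early-season metrics).
    """
    valid = series.ok_mask
    n_needed = config.window_length
    if valid.sum() < n_needed:
        raise SmoothingError(
            f"pixel {series.pixel_id}: {int(valid.sum())} valid points "
            f"< window length {n_needed}"
        )
    values = series.frame["evi"].to_numpy(dtype=float)
    filled = _interpolate_gaps(values, valid)
    smoothed = savgol_filter(
        filled, window_length=n_needed, polyorder=config.degree, mode="interp"
    )
    f = series.frame.copy()
    f["evi"] = smoothed
    f.loc[~valid, "evi"] = np.nan
    return EviTimeSeries(series.pixel_id, f, series.cadence_days)


def preprocess_series(
    series: EviTimeSeries,
    rules: QualityRules = QualityRules(),
    smoothing: SmoothingConfig = SmoothingConfig(),
    period_days: int | None = None,
) -> tuple[EviTimeSeries, FilterReport]:
    """Full preprocessing chain: optional compositing, filtering, smoothing."""
    if period_days is not None:
        series = composite_mvc(series, period_days)
    filtered, report = apply_quality_filter(series, rules)
    smoothed = smooth_savitzky_golay(filtered, smoothing)
    return smoothed, report


def make_series(
    pixel_id: str,
    dates,
    evi,
    flags=None,
    cadence_days: int = 8,
) -> EviTimeSeries:
    """Convenience constructor from parallel date / value sequences."""
    evi = np.asarray(evi, dtype=float)
    if flags is None:
        flags = np.where(np.isnan(evi), FLAG_MISSING, FLAG_OK)
    frame = pd.DataFrame({"date": pd.to_datetime(dates), "evi": evi, "flag": flags})
    return EviTimeSeries(pixel_id, frame, cadence_days)


__all__ = [
    "EviCoefficients",
    "DEFAULT_EVI_COEFFICIENTS",
    "QualityRules",
    "SmoothingConfig",
    "EviTimeSeries",
    "FilterReport",
    "SmoothingError",
    "FLAG_OK",
    "FLAG_DISCARDED",
    "FLAG_MISSING",
    "compute_evi",
    "evi_from_reflectance_table",
    "composite_mvc",
    "apply_quality_filter",
    "smooth_savitzky_golay",
    "preprocess_series",
    "make_series",
]
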
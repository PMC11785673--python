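"""Double-logistic modelling of one pixel-year of smoothed EVI composites.

The seasonal model is a greendown-capable double logistic

    f(t) = b + (A - g·(t - t_up)) · [σ_up(t) - σ_down(t)]

with σ(t) = 1 / (1 + exp(-(t - m)/s)), spring midpoint/scale (t_up, s_up),
autumn midpoint/scale (t_down, s_down), winter baseline b, seasonal amplitude
A (the envelope value at the spring midpoint) and a linear summer greendown
slope g (per day).  The linear envelope is applied smoothly over the whole
season rather than switched on at t_up: a switched envelope has a derivative
kink inside the spring segment, which corrupts the curvature-change-rate
phenometrics; away from the season the sigmoid difference vanishes, so the
two forms produce near-identical values.  With g = 0 the model reduces
exactly to the plain double logistic.  Analytic derivatives up to third
order are provided because the curvature-change-rate phenometrics are
noise-amplifying when differentiated numerically.

Fitting is bounded nonlinear least squares with a deterministic,
half-amplitude-crossing initialisation and seeded multi-start jitter; it is
exposed both as :class:`DoubleLogisticRegressor` (scikit-learn estimator API)
and the pipeline wrapper :func:`fit_double_logistic`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocessing import EviTimeSeries

logger = logging.getLogger(__name__)


class NoSeasonalityError(ValueError):
    """Raised when a pixel-year shows no usable seasonal amplitude."""


@dataclass(frozen=True)
class DoubleLogisticParams:
    """Parameters of the greendown-capable double logistic (days are DOY)."""

    baseline: float
    amplitude: float
    t_up: float
    s_up: float
    t_down: float
    s_down: float
    greendown: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.s_up <= 0 or self.s_down <= 0:
            raise ValueError("scales must be > 0")
        if not self.t_up < self.t_down:
            raise ValueError("t_up must precede t_down")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.baseline,
                self.amplitude,
                self.t_up,
                self.s_up,
                self.t_down,
                self.s_down,
                self.greendown,
            ]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "DoubleLogisticParams":
        return cls(*[float(v) for v in x])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # stable logistic
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def evaluate_curve(params: DoubleLogisticParams, t) -> np.ndarray:
    """Model value at day-of-year ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    u = _sigmoid((t - params.t_up) / params.s_up)
    d = _sigmoid((t - params.t_down) / params.s_down)
    amp = params.amplitude - params.greendown * (t - params.t_up)
    val = params.baseline + amp * (u - d)
    return val if val.ndim else float(val)


def curve_derivative(params: DoubleLogisticParams, t, order: int = 1) -> np.ndarray:
    """Analytic derivative of the model, orders 1–3."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2, or 3")
    t = np.asarray(t, dtype=float)
    u = _sigmoid((t - params.t_up) / params.s_up)
    d = _sigmoid((t - params.t_down) / params.s_down)
    su, sd = params.s_up, params.s_down
    S = u - d
    S1 = u * (1 - u) / su - d * (1 - d) / sd
    S2 = u * (1 - u) * (1 - 2 * u) / su**2 - d * (1 - d) * (1 - 2 * d) / sd**2
    S3 = (
        u * (1 - u) * (1 - 6 * u + 6 * u**2) / su**3
        - d * (1 - d) * (1 - 6 * d + 6 * d**2) / sd**3
    )
    A = params.amplitude - params.greendown * (t - params.t_up)
    A1 = -params.greendown
    if order == 1:
        val = A1 * S + A * S1
    elif order == 2:
        val = 2 * A1 * S1 + A * S2
    else:
        val = 3 * A1 * S2 + A * S3
    return val if val.ndim else float(val)


def curvature(params: DoubleLogisticParams, t) -> np.ndarray:
    """Signed curvature K = f'' / (1 + f'^2)^{3/2}."""
    f1 = curve_derivative(params, t, 1)
    f2 = curve_derivative(params, t, 2)
    return f2 / (1.0 + np.asarray(f1) ** 2) ** 1.5


def curvature_rate(params: DoubleLogisticParams, t) -> np.ndarray:
    """Rate of change of curvature, K' = [f'''(1+f'^2) - 3 f' f''^2] / (1+f'^2)^{5/2}."""
    f1 = np.asarray(curve_derivative(params, t, 1))
    f2 = np.asarray(curve_derivative(params, t, 2))
    f3 = np.asarray(curve_derivative(params, t, 3))
    val = (f3 * (1 + f1**2) - 3 * f1 * f2**2) / (1 + f1**2) ** 2.5
    return val if val.ndim else float(val)


@dataclass
class FittedCurve:
    """Daily-resolution fitted seasonal curve for one pixel-year."""

    pixel_id: str
    year: int
    doy_grid: np.ndarray
    values: np.ndarray
    params: DoubleLogisticParams
    fit_rmse: float
    converged: bool
    n_points: int = 0
    message: str = ""

    def __call__(self, t):
        return evaluate_curve(self.params, t)


@dataclass
class SeasonGeometry:
    """Trough/peak location and the annual amplitude of a fitted curve."""

    trough_doy: float
    peak_doy: float
    baseline_value: float
    peak_value: float
    boundary_warning: bool = False

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.baseline_value


@dataclass(frozen=True)
class FitConfig:
    """Bounds, tolerances and policy knobs for the seasonal fit."""

    min_points: int = 10
    amplitude_floor: float = 0.05
    baseline_bounds: tuple[float, float] = (-0.2, 0.6)
    amplitude_bounds: tuple[float, float] = (0.05, 1.2)
    scale_bounds: tuple[float, float] = (1.0, 60.0)
    greendown_bounds: tuple[float, float] = (0.0, 0.01)
    year_pad_days: int = 32
    n_starts: int = 5
    cost_tol: float = 1e-8
    seed: int = 0


DEFAULT_FIT_CONFIG = FitConfig()


def _half_crossing_init(t: np.ndarray, y: np.ndarray, b0: float, a0: float):
    thr = b0 + 0.5 * a0
    above = y >= thr
    t_up0, t_down0 = None, None
    for i in range(1, len(t)):
        if above[i] and not above[i - 1]:
            t_up0 = 0.5 * (t[i - 1] + t[i])
            break
    for i in range(len(t) - 1, 0, -1):
        if above[i - 1] and not above[i]:
            t_down0 = 0.5 * (t[i - 1] + t[i])
            break
    if t_up0 is None:
        t_up0 = float(t[np.argmax(y)]) - 30.0
    if t_down0 is None:
        t_down0 = float(t[np.argmax(y)]) + 60.0
    if t_down0 <= t_up0 + 20:
        t_down0 = t_up0 + 90.0
    return t_up0, t_down0


class DoubleLogisticRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for the greendown-capable double logistic.

    ``X`` is a single column of day-of-year values, ``y`` the vegetation
    index.  After ``fit`` the solution is available as ``params_`` (a
    :class:`DoubleLogisticParams`), ``rmse_`` and ``converged_``.

    Parameters follow :class:`FitConfig`; ``random_state`` seeds the
    multi-start jitter used when the deterministic initialisation fails to
    converge, so refits are reproducible.
    """

    def __init__(
        self,
        amplitude_floor: float = 0.05,
        baseline_bounds: tuple[float, float] = (-0.2, 0.6),
        amplitude_bounds: tuple[float, float] = (0.05, 1.2),
        scale_bounds: tuple[float, float] = (1.0, 60.0),
        greendown_bounds: tuple[float, float] = (0.0, 0.01),
        n_starts: int = 5,
        cost_tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.amplitude_floor = amplitude_floor
        self.baseline_bounds = baseline_bounds
        self.amplitude_bounds = amplitude_bounds
        self.scale_bounds = scale_bounds
        self.greendown_bounds = greendown_bounds
        self.n_starts = n_starts
        self.cost_tol = cost_tol
        self.random_state = random_state

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        order = np.argsort(t)
        t, y = t[order], y[order]

        b0 = float(np.percentile(y, 5))
        a0 = float(np.percentile(y, 95) - np.percentile(y, 5))
        if a0 < self.amplitude_floor:
            raise NoSeasonalityError(
                f"amplitude {a0:.3f} below floor {self.amplitude_floor}"
            )
        t_up0, t_down0 = _half_crossing_init(t, y, b0, a0)

        lo = np.array(
            [
                self.baseline_bounds[0],
                self.amplitude_bounds[0],
                t.min() - 1,
                self.scale_bounds[0],
                t.min() - 1,
                self.scale_bounds[0],
                self.greendown_bounds[0],
            ]
        )
        hi = np.array(
            [
                self.baseline_bounds[1],
                self.amplitude_bounds[1],
                t.max() + 1,
                self.scale_bounds[1],
                t.max() + 1,
                self.scale_bounds[1],
                self.greendown_bounds[1],
            ]
        )

        def residuals(x):
            p = x
            u = _sigmoid((t - p[2]) / p[3])
            d = _sigmoid((t - p[4]) / p[5])
            amp = p[1] - p[6] * (t - p[2])
            return p[0] + amp * (u - d) - y

        x0 = np.clip(
            np.array([b0, a0, t_up0, 10.0, t_down0, 10.0, 0.0]), lo + 1e-9, hi - 1e-9
        )
        rng = np.random.default_rng(self.random_state)
        best = None
        for attempt in range(self.n_starts):
            start = x0.copy()
            if attempt > 0:
                jitter = rng.normal(0.0, [0.02, 0.05, 8.0, 2.0, 8.0, 2.0, 0.0])
                start = np.clip(x0 + jitter, lo + 1e-9, hi - 1e-9)
            try:
                res = least_squares(
                    residuals, start, bounds=(lo, hi), ftol=self.cost_tol,
                    xtol=1e-10, gtol=1e-10,
                )
            except Exception:  # noqa: BLE001 - optimizer failure is a data problem
                continue
            if best is None or res.cost < best.cost:
                best = res
            if best.success and best.cost < max(self.cost_tol, 1e-4 * len(t)):
                break

        if best is None:
            raise NoSeasonalityError("optimizer failed on every start")
        x = best.x
        rmse = float(np.sqrt(np.mean(residuals(x) ** 2)))
        ordered = x[2] < x[4]
        self.converged_ = bool(best.success and ordered and x[1] >= self.amplitude_floor)
        if not ordered:
            # degenerate season: keep a valid params object for inspection
            x = x.copy()
            x[4] = x[2] + max(1.0, x[5])
        self.params_ = DoubleLogisticParams.from_array(x)
        self.rmse_ = rmse
        self.n_points_ = len(t)
        self.message_ = str(best.message)
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(evaluate_curve(self.params_, t))


def fit_double_logistic(
    series: EviTimeSeries,
    year: int,
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> FittedCurve:
    """Fit one pixel-year, using composites from year ± ``year_pad_days``.

    Day-of-year is counted from Jan 1 of ``year`` (Jan 1 = 1); padded
    neighbours get DOY <= 0 or > 365 so January transitions are not clipped
    by the calendar boundary.
    """
    f = series.frame
    jan1 = pd.Timestamp(year=year, month=1, day=1)
    doy = (f["date"] - jan1).dt.days.to_numpy() + 1
    days_in_year = 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365
    pad = config.year_pad_days
    window = (doy >= 1 - pad) & (doy <= days_in_year + pad)
    ok = (f["flag"] == "ok").to_numpy() & np.isfinite(f["evi"].to_numpy(dtype=float))
    use = window & ok
    in_year = use & (doy >= 1) & (doy <= days_in_year)
    if int(in_year.sum()) < config.min_points:
        raise NoSeasonalityError(
            f"pixel {series.pixel_id} year {year}: only {int(in_year.sum())} valid "
            f"points (< {config.min_points})"
        )
    t = doy[use].astype(float)
    y = f.loc[use, "evi"].to_numpy(dtype=float)

    est = DoubleLogisticRegressor(
        amplitude_floor=config.amplitude_floor,
        baseline_bounds=config.baseline_bounds,
        amplitude_bounds=config.amplitude_bounds,
        scale_bounds=config.scale_bounds,
        greendown_bounds=config.greendown_bounds,
        n_starts=config.n_starts,
        cost_tol=config.cost_tol,
        random_state=config.seed,
    )
    est.fit(t.reshape(-1, 1), y)

    grid = np.arange(1 - pad, days_in_year + pad + 1, dtype=float)
    curve = FittedCurve(
        pixel_id=series.pixel_id,
        year=year,
        doy_grid=grid,
        values=np.asarray(evaluate_curve(est.params_, grid)),
        params=est.params_,
        fit_rmse=est.rmse_,
        converged=est.converged_,
        n_points=est.n_points_,
        message=est.message_,
    )
    if not curve.converged:
        logger.warning(
            "fit pixel=%s year=%d unconverged: %s", series.pixel_id, year, est.message_
        )
    return curve


def derive_season_geometry(curve: FittedCurve) -> SeasonGeometry:
    """Locate the seasonal trough and peak of a converged daily curve.

    The peak is the curve maximum on the daily grid refined on the continuous
    model; the trough is the minimum over days before the peak.  A peak or
    trough on the first/last grid day raises the boundary flag so downstream
    metrics can be treated as low-confidence.
    """
    if not curve.converged:
        raise ValueError("season geometry requires a converged curve")
    grid, vals = curve.doy_grid, curve.values
    i_peak = int(np.argmax(vals))
    peak_doy = _refine_extremum(curve.params, grid, i_peak, maximize=True)
    before = grid < peak_doy
    if not before.any():
        raise ValueError("no days before peak; degenerate curve")
    i_trough = int(np.argmin(np.where(before, vals, np.inf)))
    trough_doy = _refine_extremum(curve.params, grid, i_trough, maximize=False)
    # the trough generically sits at the grid edge (flat winter tail); only a
    # peak on the boundary signals a truncated season
    boundary = i_peak in (0, len(grid) - 1)
    geom = SeasonGeometry(
        trough_doy=float(trough_doy),
        peak_doy=float(peak_doy),
        baseline_value=float(evaluate_curve(curve.params, trough_doy)),
        peak_value=float(evaluate_curve(curve.params, peak_doy)),
        boundary_warning=bool(boundary),
    )
    if geom.amplitude <= 0:
        raise ValueError("non-positive seasonal amplitude")
    return geom


def _refine_extremum(params, grid, i, maximize: bool) -> float:
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[i])
    sign = -1.0 if maximize else 1.0
    res = minimize_scalar(
        lambda t: sign * evaluate_curve(params, t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    # on a flat plateau keep the earliest grid day (whole-day tie rule)
    best_grid = float(evaluate_curve(params, float(grid[i])))
    refined = float(evaluate_curve(params, float(res.x)))
    if (refined - best_grid) * (-sign) > 1e-15:
        return float(res.x)
    return float(grid[i])


def params_table(curves: list[FittedCurve]) -> pd.DataFrame:
    """Long table of fitted parameters, one row per pixel-year."""
    rows = []
    for c in curves:
        p = c.params
        rows.append(
            {
                "pixel_id": c.pixel_id,
                "year": c.year,
                "baseline": p.baseline,
                "amplitude": p.amplitude,
                "t_up": p.t_up,
                "s_up": p.s_up,
                "t_down": p.t_down,
                "s_down": p.s_down,
                "greendown": p.greendown,
                "fit_rmse": c.fit_rmse,
                "converged": c.converged,
                "n_points": c.n_points,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "DoubleLogisticParams",
    "DoubleLogisticRegressor",
    "FittedCurve",
    "SeasonGeometry",
    "FitConfig",
    "DEFAULT_FIT_CONFIG",
    "NoSeasonalityError",
    "evaluate_curve",
    "curve_derivative",
    "curvature",
    "curvature_rate",
    "fit_double_logistic",
    "derive_season_geometry",
    "params_table",
]
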
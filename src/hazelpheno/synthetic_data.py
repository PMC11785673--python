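"""Synthetic EVI pixels and matched weekly ground surveys with known truth.

The generator emulates the study setting this package targets: ~20
MODIS-like pixels over hazelnut orchards on an 8-day composite cadence
(46 composites per year), a single spring green-up season per year, weekly
agronomist surveys of ten BBCH spring phases, and per-pixel hazelnut
coverage fractions.  Every pixel-year's true double-logistic parameters,
true phenometric dates (tabulated with the dense-grid brute-force reference,
not the analytic extractor, so implementation and truth stay independent)
and true phase dates are returned alongside the noisy samples.

Defaults are chosen to look like a Black-Sea hazelnut season: winter EVI
baseline 0.15–0.30, seasonal amplitude 0.3–0.6, spring midpoint DOY 85–110
(start-of-season near DOY 90–120), logistic scales 6–15 days, mild summer
greendown, Gaussian noise sd 0.02 and 10% composite dropout.

Seeding is counter-based: pixel ``i`` draws from ``SeedSequence([seed, i])``,
so adding pixels never shifts the draws of earlier pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .curvefit import DoubleLogisticParams, evaluate_curve
from .ground_obs import BBCH_ORDER
from .phenometrics import METRIC_NAMES

#: phase -> (linked true metric, mean offset in days added to the metric,
#: Gaussian jitter sd in days).  Offsets are test scaffolding, not biology:
#: they are sign-consistent with the convention bias = metric - phase, so a
#: positive offset yields a negative recovered bias.
DEFAULT_PHASE_OFFSETS: dict[str, tuple[str, float, float]] = {
    "61P": ("greenup", -15.0, 2.0),
    "64P": ("gu_ud", -2.0, 2.0),
    "67P": ("gu_ud", 20.0, 2.0),
    "03VP": ("trs2_sos", 3.0, 2.0),
    "07VP": ("trs2_sos", 14.0, 2.0),
    "70P": ("der_sos", -5.0, 2.0),
    "10V": ("trs5_sos", 0.5, 2.0),
    "13V": ("trs5_sos", 17.0, 2.0),
    "71P": ("gu_sd", 4.5, 2.0),
    "15V": ("trs5_sos", 39.0, 2.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator (days are DOY, values EVI)."""

    n_pixels: int = 20
    years: tuple[int, ...] = (2019, 2020, 2021, 2022)
    cadence_days: int = 8
    baseline_range: tuple[float, float] = (0.15, 0.30)
    amplitude_range: tuple[float, float] = (0.3, 0.6)
    t_up_range: tuple[float, float] = (85.0, 110.0)
    scale_range: tuple[float, float] = (6.0, 15.0)
    t_down_range: tuple[float, float] = (280.0, 310.0)
    greendown_range: tuple[float, float] = (0.0, 0.001)
    noise_sd: float = 0.02
    dropout_prob: float = 0.1
    understory_bump: tuple[float, float, float] | None = None  # (amp, center DOY, width)
    coverage_range: tuple[float, float] = (0.35, 1.0)
    east_fraction: float = 0.5
    east_midpoint_shift: float = 0.0  # days added to t_up for East pixels
    phase_offsets: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_OFFSETS))
    survey_weekday: int = 1  # 0 = Monday
    pad_days: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_range",
            "amplitude_range",
            "t_up_range",
            "scale_range",
            "t_down_range",
            "greendown_range",
            "coverage_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered, got {(lo, hi)}")
        if self.amplitude_range[0] <= 0:
            raise ValueError("amplitude_range must be positive")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


def _pixel_rng(seed: int, pixel_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, pixel_index]))


def _uniform(rng, bounds) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _draw_params(rng, config: SimulationConfig, east: bool) -> DoubleLogisticParams:
    t_up = _uniform(rng, config.t_up_range) + (config.east_midpoint_shift if east else 0.0)
    return DoubleLogisticParams(
        baseline=_uniform(rng, config.baseline_range),
        amplitude=_uniform(rng, config.amplitude_range),
        t_up=t_up,
        s_up=_uniform(rng, config.scale_range),
        t_down=_uniform(rng, config.t_down_range),
        s_down=_uniform(rng, config.scale_range),
        greendown=_uniform(rng, config.greendown_range),
    )


def true_metrics(params: DoubleLogisticParams, pad_days: int = 32, step: float = 0.01) -> dict:
    """Ground-truth phenometrics of a noiseless curve via the dense-grid
    brute-force reference on the padded year window."""
    return reference.dense_metrics(
        lambda t: evaluate_curve(params, t), 1 - pad_days, 365 + pad_days, step=step
    )


def pixel_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic pixel coordinates, coverage fraction and region label.

    The first ``1 - east_fraction`` of pixels sit in the West (lon ~ 31°E),
    the rest in the East (lon ~ 38°E), roughly the two Black-Sea production
    regions; coverage fractions are drawn per pixel.
    """
    rows = []
    n_west = round(config.n_pixels * (1 - config.east_fraction))
    for i in range(config.n_pixels):
        rng = _pixel_rng(config.seed, i, stream=2)
        east = i >= n_west
        lon0 = 38.0 if east else 31.0
        rows.append(
            {
                "pixel_id": f"pixel_{i:02d}",
                "lon": lon0 + 0.25 * (i % 5),
                "lat": 41.0 + 0.25 * (i // 5),
                "coverage": _uniform(rng, config.coverage_range),
                "region": "East" if east else "West",
            }
        )
    return pd.DataFrame(rows)


def simulate_series(config: SimulationConfig = SimulationConfig()):
    """Generate per-pixel EVI composite series plus a truth table.

    Returns ``(series_list, truth)`` where each series covers all configured
    years at the composite cadence (flag ``missing`` for dropouts) and
    ``truth`` has one row per pixel-year with the true parameters, the eight
    true metric dates, and the true date of every BBCH phase.
    """
    from .preprocessing import EviTimeSeries, FLAG_MISSING, FLAG_OK  # local: avoid cycle

    series_list: list[EviTimeSeries] = []
    truth_rows: list[dict] = []
    n_west = round(config.n_pixels * (1 - config.east_fraction))

    for i in range(config.n_pixels):
        pixel_id = f"pixel_{i:02d}"
        rng = _pixel_rng(config.seed, i, stream=0)
        jitter_rng = _pixel_rng(config.seed, i, stream=1)
        east = i >= n_west
        frames = []
        for year in config.years:
            params = _draw_params(rng, config, east)
            tm = true_metrics(params, pad_days=config.pad_days)
            jan1 = pd.Timestamp(year=year, month=1, day=1)
            dec31 = pd.Timestamp(year=year, month=12, day=31)
            dates = pd.date_range(jan1, dec31, freq=f"{config.cadence_days}D")
            doy = (dates - jan1).days.to_numpy() + 1.0
            values = np.asarray(evaluate_curve(params, doy))
            if config.understory_bump is not None:
                amp, center, width = config.understory_bump
                values = values + amp * np.exp(-0.5 * ((doy - center) / width) ** 2)
            values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
            dropped = rng.random(values.shape) < config.dropout_prob
            flags = np.where(dropped, FLAG_MISSING, FLAG_OK)
            values = np.where(dropped, np.nan, values)
            frames.append(pd.DataFrame({"date": dates, "evi": values, "flag": flags}))

            row = {"pixel_id": pixel_id, "year": year}
            row.update(
                {
                    "baseline": params.baseline,
                    "amplitude": params.amplitude,
                    "t_up": params.t_up,
                    "s_up": params.s_up,
                    "t_down": params.t_down,
                    "s_down": params.s_down,
                    "greendown": params.greendown,
                }
            )
            for m in METRIC_NAMES:
                row[f"true_{m}"] = tm.get(m)
            for phase in BBCH_ORDER:
                if phase not in config.phase_offsets:
                    continue
                metric, offset, jitter_sd = config.phase_offsets[phase]
                base = tm.get(metric)
                if base is None:
                    row[f"phase_{phase}"] = np.nan
                    continue
                row[f"phase_{phase}"] = base + offset + jitter_rng.normal(0.0, jitter_sd)
            truth_rows.append(row)
        frame = pd.concat(frames, ignore_index=True)
        series_list.append(EviTimeSeries(pixel_id, frame, config.cadence_days))

    return series_list, pd.DataFrame(truth_rows)


def _weekly_visits(year: int, weekday: int) -> pd.DatetimeIndex:
    # cover the phenological year including a December head and a tail for
    # late phases recorded after Dec 31 truth dates
    start = pd.Timestamp(year=year - 1, month=12, day=1)
    end = pd.Timestamp(year=year + 1, month=1, day=31)
    days = pd.date_range(start, end, freq="D")
    return days[days.weekday == weekday]


def simulate_surveys(truth: pd.DataFrame, config: SimulationConfig = SimulationConfig()) -> pd.DataFrame:
    """Weekly survey records implied by the truth table.

    Each phase is recorded on the first weekly visit on/after its true date,
    so (recorded − true) is within [0, 7) days.  Orchard ids mirror pixel
    ids (``orchard_NN`` for ``pixel_NN``).
    """
    rows = []
    for _, trow in truth.iterrows():
        pixel_id = trow["pixel_id"]
        orchard_id = pixel_id.replace("pixel", "orchard")
        year = int(trow["year"])
        visits = _weekly_visits(year, config.survey_weekday)
        jan1 = pd.Timestamp(year=year, month=1, day=1)
        for phase in BBCH_ORDER:
            col = f"phase_{phase}"
            if col not in trow or pd.isna(trow[col]):
                continue
            true_date = jan1 + pd.Timedelta(days=float(trow[col]) - 1)
            later = visits[visits >= true_date]
            if len(later) == 0:
                continue
            rows.append({"orchard_id": orchard_id, "date": later[0], "code": phase})
    return pd.DataFrame(rows, columns=["orchard_id", "date", "code"])


def link_table(config: SimulationConfig = SimulationConfig()) -> pd.DataFrame:
    """Identity orchard <-> pixel link used by the matchup stage."""
    return pd.DataFrame(
        {
            "pixel_id": [f"pixel_{i:02d}" for i in range(config.n_pixels)],
            "orchard_id": [f"orchard_{i:02d}" for i in range(config.n_pixels)],
        }
    )


__all__ = [
    "SimulationConfig",
    "DEFAULT_PHASE_OFFSETS",
    "simulate_series",
    "simulate_surveys",
    "true_metrics",
    "pixel_metadata",
    "link_table",
]
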
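import numpy as np
import pandas as pd
import pytest

from hazelpheno.curvefit import DoubleLogisticParams, FittedCurve, evaluate_curve
from hazelpheno.preprocessing import EviTimeSeries


def curve_from_params(
    params: DoubleLogisticParams,
    pixel_id: str = "px",
    year: int = 2021,
    pad: int = 32,
) -> FittedCurve:
    """Converged FittedCurve built directly from known parameters."""
    grid = np.arange(1 - pad, 365 + pad + 1, dtype=float)
    return FittedCurve(
        pixel_id=pixel_id,
        year=year,
        doy_grid=grid,
        values=np.asarray(evaluate_curve(params, grid)),
        params=params,
        fit_rmse=0.0,
        converged=True,
    )


def random_params(rng: np.random.Generator) -> DoubleLogisticParams:
    """Season parameters drawn over the generator's realistic ranges."""
    return DoubleLogisticParams(
        baseline=rng.uniform(0.15, 0.30),
        amplitude=rng.uniform(0.3, 0.6),
        t_up=rng.uniform(85, 110),
        s_up=rng.uniform(6, 15),
        t_down=rng.uniform(280, 310),
        s_down=rng.uniform(6, 15),
        greendown=rng.uniform(0.0, 0.001),
    )


@pytest.fixture
def logistic_limb():
    """Single rising logistic: autumn limb pushed past the padded year end,
    so closed forms for the spring metrics hold."""
    return DoubleLogisticParams(
        baseline=0.2, amplitude=0.5, t_up=100.0, s_up=10.0,
        t_down=360.0, s_down=5.0, greendown=0.0,
    )


@pytest.fixture
def limb_curve(logistic_limb):
    return curve_from_params(logistic_limb)


def series_from_curve(
    params: DoubleLogisticParams,
    year: int = 2021,
    cadence: int = 8,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel_id: str = "px",
) -> EviTimeSeries:
    jan1 = pd.Timestamp(year=year, month=1, day=1)
    dates = pd.date_range(jan1, pd.Timestamp(year=year, month=12, day=31), freq=f"{cadence}D")
    doy = (dates - jan1).days.to_numpy() + 1.0
    vals = np.asarray(evaluate_curve(params, doy))
    if noise_sd > 0:
        vals = vals + (rng or np.random.default_rng(0)).normal(0, noise_sd, vals.shape)
    frame = pd.DataFrame({"date": dates, "evi": vals, "flag": "ok"})
    return EviTimeSeries(pixel_id, frame, cadence)
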
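"""Pipeline orchestration and map export.

``run_pipeline`` chains preprocess -> fit -> extract -> onsets -> compare on
the files named in a :class:`~hazelpheno.io.PipelineConfig`, writing every
intermediate as CSV plus a structured run log; per-pixel-year failures are
logged and skipped, the run only aborts on unreadable input.
``export_sos_map`` writes a (lon, lat, doy) point table and, when the pixels
form a regular grid, an ESRI ASCII raster.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import compare_all
from .curvefit import FitConfig, NoSeasonalityError, fit_double_logistic, params_table
from .ground_obs import load_observations, phase_onsets
from .io import PipelineConfig, read_series_csv, read_table, write_table
from .phenometrics import extract_all, metrics_table
from .preprocessing import SmoothingError, apply_quality_filter, composite_mvc, smooth_savitzky_golay

logger = logging.getLogger(__name__)


def _log_event(log_lines: list, stage: str, **kv) -> None:
    entry = {"stage": stage, **kv}
    log_lines.append(json.dumps(entry, sort_keys=True, default=str))
    logger.info("%s %s", stage, kv)


def process_series(series_list, config: PipelineConfig, log_lines: list):
    """Preprocess + fit + extract for every pixel-year; returns
    (smoothed series, filter reports, fitted curves, phenometric sets)."""
    smoothed_list, reports, curves, sets = [], [], [], []
    for series in series_list:
        if config.period_days is not None:
            series = composite_mvc(series, config.period_days)
        filtered, report = apply_quality_filter(series, config.quality)
        reports.append(report)
        _log_event(
            log_lines, "filter", pixel_id=series.pixel_id,
            discarded=report.n_discarded, total=report.n_total,
        )
        try:
            smooth = smooth_savitzky_golay(filtered, config.smoothing)
        except SmoothingError as exc:
            _log_event(log_lines, "smooth_skip", pixel_id=series.pixel_id, reason=str(exc))
            continue
        smoothed_list.append(smooth)
        for year in smooth.years():
            try:
                curve = fit_double_logistic(
                    smooth, year,
                    FitConfig(min_points=config.min_fit_points, seed=config.seed),
                )
            except NoSeasonalityError as exc:
                _log_event(
                    log_lines, "fit_skip", pixel_id=series.pixel_id, year=year,
                    reason=str(exc),
                )
                continue
            curves.append(curve)
            _log_event(
                log_lines, "fit", pixel_id=series.pixel_id, year=year,
                rmse=round(curve.fit_rmse, 6), converged=curve.converged,
            )
            sets.append(extract_all(curve))
    return smoothed_list, reports, curves, sets


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    _log_event(
        log_lines, "start", version=__version__, seed=config.seed,
        config_hash=config.digest(), python=platform.python_version(),
    )

    series_list = read_series_csv(config.series_csv)
    good_series = []
    for s in series_list:
        if s.frame["evi"].notna().sum() == 0:
            _log_event(log_lines, "series_skip", pixel_id=s.pixel_id, reason="no values")
            continue
        good_series.append(s)

    smoothed, reports, curves, sets = process_series(good_series, config, log_lines)

    filter_rows = []
    for r in reports:
        for rule, count in r.per_rule.items():
            filter_rows.append({"pixel_id": r.pixel_id, "rule": rule, "count": count})
        filter_rows.append(
            {"pixel_id": r.pixel_id, "rule": "total_unique", "count": r.n_discarded}
        )
    write_table(pd.DataFrame(filter_rows), out / "filter_report.csv")
    write_table(params_table(curves), out / "fit_params.csv")
    metrics = metrics_table(sets, round_days=False)
    write_table(metrics, out / "phenometrics.csv")

    comparison = pd.DataFrame()
    if config.surveys_csv:
        surveys = read_table(config.surveys_csv)
        obs, qc = load_observations(surveys)
        _log_event(
            log_lines, "ground_obs", mapped=qc.n_mapped, unmapped=qc.n_unmapped,
            duplicates=qc.n_duplicates,
        )
        onsets = phase_onsets(obs, rule=config.onset_rule)
        write_table(onsets, out / "phase_onsets.csv")
        link = read_table(config.link_csv) if config.link_csv else None
        coverage = None
        if config.stratify_coverage and config.metadata_csv:
            coverage = read_table(config.metadata_csv)
        comparison = compare_all(
            metrics, onsets, link=link, metric_names=config.metric_names,
            coverage=coverage, coverage_threshold=config.coverage_threshold,
            seed=config.seed,
        )
        write_table(comparison, out / "comparison.csv")

    _log_event(
        log_lines, "done", n_series=len(good_series), n_curves=len(curves),
        n_comparison_rows=len(comparison),
    )
    (out / "run_log.jsonl").write_text("\n".join(log_lines) + "\n")
    return out


def export_sos_map(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    metric: str = "trs5_sos",
    out_prefix=None,
    year: int | None = None,
    nodata: float = -9999.0,
):
    """Join one phenometric with pixel coordinates and export a map.

    Returns the (lon, lat, doy) point table; when ``out_prefix`` is given
    writes ``<prefix>_points.csv`` and, if the pixels form a regular
    lon/lat grid, ``<prefix>.asc`` (ESRI ASCII raster, missing metrics as
    the nodata value).  Irregular layouts fall back to the point table with
    a warning.
    """
    if metric not in metrics.columns:
        raise ValueError(f"unknown metric {metric!r}")
    m = metrics.copy()
    if year is not None:
        m = m[m["year"] == year]
    m = m.groupby("pixel_id", as_index=False)[metric].mean()
    pts = metadata.merge(m, on="pixel_id", how="left")[
        ["pixel_id", "lon", "lat", metric]
    ].rename(columns={metric: "doy"})
    if out_prefix is not None:
        write_table(pts, f"{out_prefix}_points.csv")
        grid = _regular_grid(pts, nodata)
        if grid is None:
            logger.warning("pixels do not form a regular grid; point table only")
        else:
            Path(f"{out_prefix}.asc").write_text(grid)
    return pts


def _regular_grid(pts: pd.DataFrame, nodata: float) -> str | None:
    lons = np.sort(pts["lon"].unique())
    lats = np.sort(pts["lat"].unique())
    if len(lons) < 2 or len(lats) < 2:
        return None
    dx = np.diff(lons)
    dy = np.diff(lats)
    if not (np.allclose(dx, dx[0]) and np.allclose(dy, dy[0]) and np.isclose(dx[0], dy[0])):
        return None
    if len(pts) != len(lons) * len(lats) or pts.duplicated(["lon", "lat"]).any():
        return None
    cell = float(dx[0])
    arr = np.full((len(lats), len(lons)), nodata)
    li = {v: k for k, v in enumerate(lons)}
    la = {v: k for k, v in enumerate(lats)}
    for _, r in pts.iterrows():
        v = r["doy"]
        arr[la[r["lat"]], li[r["lon"]]] = nodata if pd.isna(v) else float(v)
    lines = [
        f"ncols {len(lons)}",
        f"nrows {len(lats)}",
        f"xllcorner {lons[0] - cell / 2}",
        f"yllcorner {lats[0] - cell / 2}",
        f"cellsize {cell}",
        f"NODATA_value {nodata}",
    ]
    for row in arr[::-1]:  # ASCII grids run north -> south
        lines.append(" ".join(f"{v:g}" for v in row))
    return "\n".join(lines) + "\n"


__all__ = ["run_pipeline", "process_series", "export_sos_map"]
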
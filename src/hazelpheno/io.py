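"""CSV readers/writers and run configuration.

All interchange is comma-separated UTF-8 with a mandatory header and '.'
decimals; dates are ISO-8601 in files, metric outputs are day-of-year
(Jan 1 = 1).  Each writer's output is readable by its paired reader with
lossless field values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .preprocessing import EviTimeSeries, QualityRules, SmoothingConfig, evi_from_reflectance_table


def read_series_csv(path) -> list[EviTimeSeries]:
    """Read a pixel time-series table into one series per pixel.

    Columns: ``pixel_id``, ``date`` and either ``evi`` or
    ``rho_nir``/``rho_red``/``rho_blue`` (EVI is then computed), optional
    ``qa`` and ``flag``.
    """
    df = pd.read_csv(path, dtype={"pixel_id": str})
    if "evi" not in df.columns:
        if not {"rho_nir", "rho_red", "rho_blue"}.issubset(df.columns):
            raise ValueError(
                f"{path}: need an 'evi' column or rho_nir/rho_red/rho_blue"
            )
        df = evi_from_reflectance_table(df)
    if "flag" not in df.columns:
        df["flag"] = "ok"
        df.loc[df["evi"].isna(), "flag"] = "missing"
    out = []
    for pixel_id, g in df.groupby("pixel_id", sort=True):
        out.append(EviTimeSeries(str(pixel_id), g[["date", "evi", "flag"]].copy()))
    return out


def write_series_csv(series_list: list[EviTimeSeries], path) -> None:
    frames = []
    for s in series_list:
        f = s.frame.copy()
        f.insert(0, "pixel_id", s.pixel_id)
        frames.append(f)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["pixel_id", "date", "evi", "flag"]
    )
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("pixel_id", "orchard_id", "code", "bbch"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def write_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    series_csv: str = ""
    surveys_csv: str = ""
    metadata_csv: str = ""
    link_csv: str = ""
    out_dir: str = "pipeline_out"
    period_days: int | None = None  # set to composite raw (e.g. daily) input
    quality: QualityRules = field(default_factory=QualityRules)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    onset_rule: str = "first-seen"
    min_fit_points: int = 10
    coverage_threshold: float = 0.75
    stratify_coverage: bool = False
    metric_names: tuple = (
        "der_sos", "der_pos", "trs2_sos", "trs5_sos",
        "gu_ud", "gu_sd", "greenup", "maturity",
    )
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if isinstance(raw.get("quality"), dict):
            q = dict(raw["quality"])
            if "summer_window" in q:
                q["summer_window"] = tuple(tuple(x) for x in q["summer_window"])
            raw["quality"] = QualityRules(**q)
        if isinstance(raw.get("smoothing"), dict):
            raw["smoothing"] = SmoothingConfig(**raw["smoothing"])
        if "metric_names" in raw:
            raw["metric_names"] = tuple(raw["metric_names"])
        return cls(**raw)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metric_names"] = list(self.metric_names)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_table",
    "write_table",
    "PipelineConfig",
]
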
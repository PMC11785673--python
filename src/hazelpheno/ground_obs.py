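"""Weekly orchard phenology surveys: scale mapping and phase-onset dates.

Surveys record a phase code (source scale) per orchard visit; codes are
mapped to 3-digit BBCH codes and reduced to one onset date per
orchard-year-phase.  Ten hazelnut spring phases are modelled: the female
reproductive track (61P begin flowering … 71P clusters visible) and the
vegetative track (03VP swollen buds … 15V more leaves unfolded).

Because female flowering brackets the calendar boundary, December
observations can be assigned to the following phenological year, in which
case their day-of-year is negative (Dec 20 -> -11); this keeps
December-vs-January date differences free of a ~330-day wrap artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPRODUCTIVE = ("61P", "64P", "67P", "70P", "71P")
VEGETATIVE = ("03VP", "07VP", "10V", "13V", "15V")

#: canonical emission order, roughly chronological through spring
BBCH_ORDER = ("61P", "64P", "67P", "03VP", "07VP", "70P", "10V", "13V", "71P", "15V")

CATEGORY = {**{c: "reproductive" for c in REPRODUCTIVE}, **{c: "vegetative" for c in VEGETATIVE}}


def phase_category(code: str) -> str:
    """'reproductive' for the P-suffixed 6x/7x codes, 'vegetative' for VP/V."""
    try:
        return CATEGORY[code]
    except KeyError:
        raise ValueError(f"unknown BBCH code {code!r}") from None


@dataclass
class ScaleMapping:
    """Source-scale code -> BBCH code lookup (many-to-one)."""

    table: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ScaleMapping":
        """Identity mapping over the ten modelled BBCH codes, shipped as an
        editable CSV in the package data."""
        with resources.files("hazelpheno.data").joinpath("bbch_mapping.csv").open() as fh:
            df = pd.read_csv(fh, dtype=str)
        return cls(dict(zip(df["source_code"], df["bbch_code"])))

    @classmethod
    def from_csv(cls, path) -> "ScaleMapping":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["source_code"], df["bbch_code"])))

    def map(self, code: str) -> str | None:
        return self.table.get(code)


@dataclass
class QCReport:
    """Counts from survey-table loading."""

    n_rows: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_duplicates: int = 0
    n_rejected_dates: int = 0
    unmapped_codes: tuple = ()


def load_observations(
    table: pd.DataFrame, mapping: ScaleMapping | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Map and de-duplicate a raw survey table.

    ``table`` needs columns ``orchard_id``, ``date``, ``code``.  Rows with
    unparseable dates are rejected (and counted); duplicate
    (orchard, date, code) rows collapse to one; unmapped codes are preserved
    with ``bbch`` = NaN and reported.
    """
    if mapping is None:
        mapping = ScaleMapping.default()
    required = {"orchard_id", "date", "code"}
    if not required.issubset(table.columns):
        raise ValueError(f"survey table must have columns {sorted(required)}")
    df = table.copy()
    n_rows = len(df)
    parsed = pd.to_datetime(df["date"], errors="coerce")
    rejected = parsed.isna()
    for _, row in df.loc[rejected].iterrows():
        logger.warning("rejected survey row with unparseable date: %r", row.to_dict())
    df = df.loc[~rejected].copy()
    df["date"] = parsed[~rejected]
    df["code"] = df["code"].astype(str)
    before = len(df)
    df = df.drop_duplicates(subset=["orchard_id", "date", "code"]).reset_index(drop=True)
    n_dup = before - len(df)
    df["bbch"] = df["code"].map(mapping.table)
    unmapped = df["bbch"].isna()
    report = QCReport(
        n_rows=n_rows,
        n_mapped=int((~unmapped).sum()),
        n_unmapped=int(unmapped.sum()),
        n_duplicates=n_dup,
        n_rejected_dates=int(rejected.sum()),
        unmapped_codes=tuple(sorted(df.loc[unmapped, "code"].unique())),
    )
    return df, report


def _phenological_year_and_doy(
    dates: pd.Series, december_to_next_year: bool
) -> tuple[np.ndarray, np.ndarray]:
    year = dates.dt.year.to_numpy()
    doy = dates.dt.dayofyear.to_numpy().astype(float)
    if december_to_next_year:
        dec = dates.dt.month.to_numpy() == 12
        days_in_year = np.where(dates.dt.is_leap_year.to_numpy(), 366.0, 365.0)
        year = np.where(dec, year + 1, year)
        doy = np.where(dec, doy - days_in_year, doy)
    return year, doy


def phase_onsets(
    observations: pd.DataFrame,
    rule: str = "first-seen",
    december_to_next_year: bool = True,
) -> pd.DataFrame:
    """Reduce mapped observations to one onset per (orchard, year, phase).

    ``first-seen`` takes the earliest day-of-year the phase was recorded
    (the phenology convention for "beginning of stage"; with weekly visits it
    overestimates the true onset by at most 7 days); ``median-seen`` takes
    the median recorded day.  Phases never observed in an orchard-year simply
    have no row.
    """
    if rule not in ("first-seen", "median-seen"):
        raise ValueError(f"unknown onset rule {rule!r}")
    df = observations.dropna(subset=["bbch"]).copy()
    if df.empty:
        return pd.DataFrame(columns=["orchard_id", "year", "bbch", "onset_doy", "n_obs"])
    year, doy = _phenological_year_and_doy(df["date"], december_to_next_year)
    df["year"] = year
    df["doy"] = doy
    agg = "min" if rule == "first-seen" else "median"
    out = (
        df.groupby(["orchard_id", "year", "bbch"], sort=True)["doy"]
        .agg([(agg, agg), ("n_obs", "size")])
        .reset_index()
        .rename(columns={agg: "onset_doy"})
    )
    out["year"] = out["year"].astype(int)
    out["n_obs"] = out["n_obs"].astype(int)
    return out[["orchard_id", "year", "bbch", "onset_doy", "n_obs"]]


__all__ = [
    "REPRODUCTIVE",
    "VEGETATIVE",
    "BBCH_ORDER",
    "phase_category",
    "ScaleMapping",
    "QCReport",
    "load_observations",
    "phase_onsets",
]
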
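"""Death-record filtering, daily aggregation, and case-crossover stratum assignment.

Non-accidental deaths (ICD-10 chapters A through R, i.e. codes A00-R99) are
kept, records with missing or invalid municipality or date are excluded with a
logged reason, counts are aggregated to zero-filled per-municipality daily
series (optionally split by an effect-modifier column under complete-case
rules), and every observation day is assigned its space-time stratum:
municipality x year x month x day-of-week. Within a stratum, each case day is
compared only to the other same-weekday days of the same municipality-month,
which is what eliminates slow confounding (trend, season) and the weekly cycle
from the conditional fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exposure import ValidationError

__all__ = [
    "DeathCountSeries",
    "include_nonaccidental",
    "filter_records",
    "aggregate_counts",
    "assign_strata",
    "read_death_records",
    "write_count_table",
]

MODIFIER_DOMAINS: Mapping[str, tuple[str, ...]] = {
    "sex": ("men", "women"),
    "age_group": ("<60", ">=60"),
    "race": ("White", "Black"),
    "income_tertile": ("1", "2", "3"),
    "residence": ("urban", "rural"),
    "utilities": ("all", "lacking"),
}

# 5-category race/colour recode: Parda and Black are analysed jointly as Black;
# Indigenous and Asian are excluded from subgroup runs (kept in overall runs).
RACE_RECODE: Mapping[str, str | None] = {
    "White": "White",
    "Black": "Black",
    "Parda": "Black",
    "Indigenous": None,
    "Asian": None,
}


@dataclass
class DeathCountSeries:
    """Zero-filled daily death counts for one municipality (and subgroup)."""

    municipality_id: str
    subgroup: str  # "all" or "modifier=level"
    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.counts = np.asarray(self.counts)
        if len(self.dates) != len(self.counts):
            raise ValidationError("dates/counts length mismatch")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        diffs = np.diff(self.dates.values.astype("datetime64[D]").astype(int))
        if len(diffs) and not np.all(diffs == 1):
            raise ValidationError(
                f"municipality {self.municipality_id}: count dates not contiguous"
            )

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def include_nonaccidental(icd10: str) -> bool:
    """True iff the code's chapter letter falls in A..R (non-accidental causes).

    The rule acts on the first character only, after upper-casing, so codes of
    any length ("R99", "R991") are classified by chapter prefix.
    """
    if not isinstance(icd10, str) or len(icd10) == 0 or not icd10[0].isalpha():
        raise ValidationError(f"malformed ICD-10 code: {icd10!r}")
    return "A" <= icd10[0].upper() <= "R"


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the inclusion rules; nothing raises, every drop is logged.

    Exclusion reasons: ``missing_municipality``, ``missing_date``,
    ``invalid_date``, ``invalid_icd10``, ``external_cause``.
    Returns (kept records with parsed ``date`` column, exclusion log).
    """
    df = records.copy()
    n = len(df)
    reasons = pd.Series("", index=df.index, dtype=object)

    muni = df.get("municipality_id", pd.Series(np.nan, index=df.index))
    muni_missing = muni.isna() | (muni.astype(str).str.strip() == "")
    reasons[muni_missing & (reasons == "")] = "missing_municipality"

    raw_date = df.get("date", pd.Series(np.nan, index=df.index))
    date_missing = raw_date.isna() | (raw_date.astype(str).str.strip() == "")
    reasons[date_missing & (reasons == "")] = "missing_date"
    parsed = pd.to_datetime(raw_date, format="%Y-%m-%d", errors="coerce")
    reasons[(~date_missing) & parsed.isna() & (reasons == "")] = "invalid_date"

    icd = df.get("icd10", pd.Series("", index=df.index)).astype(str).str.strip()
    first = icd.str.slice(0, 1)
    malformed = (icd == "") | (icd.str.lower() == "nan") | ~first.str.isalpha()
    reasons[malformed & (reasons == "")] = "invalid_icd10"
    chapter = first.str.upper()
    external = ~malformed & ~chapter.between("A", "R")
    reasons[external & (reasons == "")] = "external_cause"

    kept = df.loc[reasons == ""].copy()
    kept["date"] = parsed.loc[kept.index]
    kept["municipality_id"] = kept["municipality_id"].astype(str)
    log = reasons[reasons != ""].value_counts()
    log.index.name = "reason"
    log.name = "count"
    assert len(kept) + int(log.sum()) == n
    return kept, log


def recode_race(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse a raw 5-category race/colour column to {White, Black}.

    Parda joins Black; Indigenous and Asian become missing for subgroup
    purposes. Returns the recoded frame and the number of records recoded to
    missing.
    """
    df = records.copy()
    if "race" not in df.columns:
        return df, 0
    mapped = df["race"].map(lambda v: RACE_RECODE.get(v, v) if pd.notna(v) else v)
    n_excluded = int((df["race"].notna() & mapped.isna()).sum())
    df["race"] = mapped
    return df, n_excluded


def aggregate_counts(
    records: pd.DataFrame,
    window: tuple,
    subgroup_by: str | None = None,
) -> tuple[list[DeathCountSeries], int]:
    """Aggregate filtered records to zero-filled daily series per municipality.

    With ``subgroup_by``, one series per (municipality, level) is produced and
    records missing that modifier are dropped complete-case; the dropped count
    is returned alongside the series.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    full_index = pd.date_range(start, end, freq="D")
    if len(records):
        dates = pd.to_datetime(records["date"])
        if dates.min() < start or dates.max() > end:
            raise ValidationError(
                f"analysis window [{start.date()}, {end.date()}] does not cover "
                f"record dates [{dates.min().date()}, {dates.max().date()}]"
            )

    n_incomplete = 0
    df = records
    if subgroup_by is not None:
        if subgroup_by not in records.columns:
            raise ValidationError(f"modifier column {subgroup_by!r} not present")
        missing = records[subgroup_by].isna() | (
            records[subgroup_by].astype(str).str.strip() == ""
        )
        n_incomplete = int(missing.sum())
        df = records.loc[~missing]

    out: list[DeathCountSeries] = []
    if len(df) == 0:
        return out, n_incomplete
    keys = ["municipality_id"] + ([subgroup_by] if subgroup_by else [])
    for key, g in df.groupby(keys, sort=True):
        if subgroup_by:
            muni, level = str(key[0]), f"{subgroup_by}={key[1]}"
        else:
            muni = str(key[0]) if isinstance(key, tuple) else str(key)
            level = "all"
        counts = (
            g.groupby(pd.to_datetime(g["date"])).size().reindex(full_index, fill_value=0)
        )
        out.append(DeathCountSeries(muni, level, full_index, counts.values))
    return out, n_incomplete


def assign_strata(
    dates: pd.DatetimeIndex, municipality_id: str | None = None
) -> pd.Series:
    """Space-time stratum label per date: municipality / year / month / ISO weekday.

    ISO weekday numbering (Monday = 1). Any consistent weekday convention
    yields identical strata; ISO is used for portability of the labels.
    """
    dates = pd.DatetimeIndex(dates)
    prefix = f"{municipality_id}/" if municipality_id is not None else ""
    labels = (
        prefix
        + dates.year.astype(str)
        + "-"
        + dates.month.astype(str).str.zfill(2)
        + "/dow"
        + (dates.dayofweek + 1).astype(str)
    )
    return pd.Series(labels, index=dates, name="stratum")


def read_death_records(path) -> pd.DataFrame:
    """Read a delimited death-record table; extra modifier columns pass through."""
    return pd.read_csv(path, dtype={"municipality_id": str, "date": str, "icd10": str})


def write_count_table(series: Iterable[DeathCountSeries], path) -> None:
    """Long-format export: municipality_id, subgroup, date, count, stratum_id."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "municipality_id": s.municipality_id,
                    "subgroup": s.subgroup,
                    "date": s.dates.strftime("%Y-%m-%d"),
                    "count": s.counts,
                    "stratum_id": assign_strata(s.dates, s.municipality_id).values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
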
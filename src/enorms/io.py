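"""Measurement tables: loading, validation, stratification, filtering.

A measurement table is long-format: one row per subject x nerve x measure,
with demographic metadata (age, height, sex) and a cohort flag separating
historical patient data from directly sampled healthy controls.  Measure
semantics (pathological direction, units) live here: amplitudes and
conduction velocities are abnormal below their lower limit, latencies above
their upper limit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    EmptyInputError,
    InsufficientSampleError,
    SchemaError,
)

__all__ = [
    "MeasureMeta",
    "MEASURE_META",
    "StratumSpec",
    "DEFAULT_STRATA",
    "LoadReport",
    "MeasurementTable",
    "read_table",
    "write_table",
    "exclude_subjects",
    "stratify",
    "require_min_n",
]

COLUMNS = ["subject_id", "age", "height", "sex", "nerve", "measure_kind", "value", "cohort"]

SEXES = {"female", "male", "unknown"}
COHORTS = {"historical", "control"}


@dataclass(frozen=True)
class MeasureMeta:
    """Semantics of one measure kind: its units and pathological side."""

    measure_kind: str
    abnormal_direction: str  # low | high
    unit: str


#: Built-in nerve-conduction measure kinds.  Amplitudes and conduction
#: velocities fall with pathology (lower limit); latencies rise (upper limit).
MEASURE_META: dict[str, MeasureMeta] = {
    "motor_amplitude": MeasureMeta("motor_amplitude", "low", "mV"),
    "sensory_amplitude": MeasureMeta("sensory_amplitude", "low", "µV"),
    "conduction_velocity": MeasureMeta("conduction_velocity", "low", "m/s"),
    "f_min_latency": MeasureMeta("f_min_latency", "high", "ms"),
    "distal_latency": MeasureMeta("distal_latency", "high", "ms"),
}


@dataclass(frozen=True)
class StratumSpec:
    """Ordered age strata with inclusive integer-year bounds."""

    strata: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        seen_years: set[int] = set()
        for label, lo, hi in self.strata:
            if lo > hi:
                raise ConfigError(f"stratum {label!r}: min {lo} > max {hi}")
            years = set(range(int(lo), int(hi) + 1))
            if years & seen_years:
                raise ConfigError(f"stratum {label!r} overlaps an earlier stratum")
            seen_years |= years

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.strata]

    def assign(self, age: float) -> str | None:
        """Stratum label containing floor(age), or None if age falls in a gap."""
        year = math.floor(age)
        for label, lo, hi in self.strata:
            if lo <= year <= hi:
                return label
        return None


#: The age stratification used for lower-limb nerve-conduction limits:
#: children/adolescents and two adult bands.  Ages 19 and >60 fall in gaps
#: and are dropped with a logged count.
DEFAULT_STRATA = StratumSpec((("9-18", 9, 18), ("20-44", 20, 44), ("45-60", 45, 60)))


@dataclass
class LoadReport:
    rows_read: int = 0
    rows_dropped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, count: int = 1) -> None:
        if count:
            self.rows_dropped += count
            self.reasons[reason] = self.reasons.get(reason, 0) + count

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_dropped": self.rows_dropped,
            "reasons": dict(self.reasons),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class MeasurementTable:
    """Thin wrapper over a long-format measurement DataFrame.

    Rows keep file order.  Duplicate (subject, nerve, measure) rows are
    retained by default — historical data may contain repeat visits — and can
    be collapsed with :meth:`dedupe`.
    """

    def __init__(self, df: pd.DataFrame, report: LoadReport | None = None):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"measurement table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.report = report or LoadReport(rows_read=len(df))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, MeasurementTable) and self.df.equals(other.df)

    @property
    def subjects(self) -> set[str]:
        return set(self.df["subject_id"])

    def values_for(self, nerve: str, measure_kind: str) -> np.ndarray:
        sel = (self.df["nerve"] == nerve) & (self.df["measure_kind"] == measure_kind)
        return self.df.loc[sel, "value"].to_numpy(dtype=float)

    def groups(self) -> Iterable[tuple[tuple[str, str], "MeasurementTable"]]:
        """Iterate (nerve, measure_kind) groups in first-appearance order."""
        for key, sub in self.df.groupby(["nerve", "measure_kind"], sort=False):
            yield key, MeasurementTable(sub)

    def filter_cohort(self, cohort: str) -> "MeasurementTable":
        return MeasurementTable(self.df[self.df["cohort"] == cohort])

    def dedupe(self, keep: str = "none") -> "MeasurementTable":
        """Collapse repeat (subject, nerve, measure) rows; 'none' keeps all."""
        if keep == "none":
            return self
        if keep not in ("first", "last"):
            raise ConfigError(f"dedupe must be first|last|none, got {keep!r}")
        return MeasurementTable(
            self.df.drop_duplicates(
                subset=["subject_id", "nerve", "measure_kind"], keep=keep
            )
        )


def read_table(
    path, schema: Mapping[str, str] | None = None
) -> MeasurementTable:
    """Load a measurement CSV with an optional column-name mapping.

    ``schema`` maps canonical column names (subject_id, age, height, sex,
    nerve, measure_kind, value, cohort) to the file's column names; omitted
    entries use the canonical names.  Rows with non-parseable or invalid
    values (non-numeric, negative, non-finite value; negative age) are
    dropped and counted in the table's :class:`LoadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    if raw.empty:
        raise EmptyInputError(f"{path} contains no data rows")

    mapping = {c: c for c in COLUMNS}
    if schema:
        mapping.update(schema)
    for canonical, source in mapping.items():
        if canonical in ("height",) and source not in raw.columns:
            continue  # height is optional
        if source not in raw.columns:
            raise SchemaError(
                f"mapped column {source!r} (for {canonical!r}) not found in {path.name}"
            )

    report = LoadReport(rows_read=len(raw))
    df = pd.DataFrame(
        {
            canonical: raw[source]
            if source in raw.columns
            else pd.Series([""] * len(raw))
            for canonical, source in mapping.items()
        }
    )
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["height"] = pd.to_numeric(df["height"], errors="coerce")

    bad_value = ~np.isfinite(df["value"]) | (df["value"] < 0)
    report.drop("unparseable_or_negative_value", int(bad_value.sum()))
    bad_age = ~np.isfinite(df["age"]) | (df["age"] < 0)
    report.drop("unparseable_or_negative_age", int((bad_age & ~bad_value).sum()))
    df = df[~bad_value & ~bad_age].copy()

    df["sex"] = df["sex"].where(df["sex"].isin(SEXES), "unknown")
    df["cohort"] = df["cohort"].where(df["cohort"].isin(COHORTS), "historical")
    return MeasurementTable(df, report)


def write_table(table: MeasurementTable, path) -> None:
    table.df.to_csv(Path(path), index=False)


def exclude_subjects(
    table: MeasurementTable, ids: set[str]
) -> tuple[MeasurementTable, int]:
    """Drop all rows of the given subjects (e.g. healthy controls present in
    the historical dataset, removed to avoid bias).

    Returns the filtered table and the number of rows removed.
    """
    if not ids:
        return table, 0
    keep = ~table.df["subject_id"].isin(ids)
    removed = int((~keep).sum())
    return MeasurementTable(table.df[keep]), removed


def stratify(
    table: MeasurementTable, spec: StratumSpec = DEFAULT_STRATA
) -> tuple[dict[str, MeasurementTable], int]:
    """Partition a table into age strata by floor(age) against inclusive
    integer bounds.

    Rows whose (floored) age falls in a gap between strata are dropped;
    their count is returned alongside the per-stratum tables (every stratum
    label is present, possibly empty).
    """
    labels = table.df["age"].map(spec.assign)
    out = {
        label: MeasurementTable(table.df[labels == label])
        for label in spec.labels
    }
    dropped = int(labels.isna().sum())
    return out, dropped


def require_min_n(table: MeasurementTable, min_n: int = 100) -> MeasurementTable:
    """Gate a group on sample size: pass through iff n is strictly greater
    than ``min_n`` (default 100), else raise :class:`InsufficientSampleError`.
    """
    if len(table) <= min_n:
        raise InsufficientSampleError(n=len(table), min_n=min_n)
    return table
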
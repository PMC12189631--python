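"""Domain types and delimited-text I/O for automated-weighing-system (AWS) data.

An AWS is a load-cell platform at a feeder station that records an animal's
weight at every visit.  The package works on four tables, all plain CSV with
a header row and ISO-8601 timestamps:

* **records** — raw AWS measurements: ``animal_id, timestamp, weight_kg,
  concurrent_forage``.  The boolean flag marks measurements taken while a
  forage-intake monitoring system was active on the same platform (those are
  screened out before any statistics).
* **references** — static-scale ground truth: ``animal_id, date, weight_kg``,
  one row per animal per measurement campaign, taken at the mid-date of a
  measurement window.
* **daily weights** — per-animal per-calendar-day means produced by
  pre-processing.
* **ADG table** — target average-daily-gain (kg/day) by live-weight class,
  from national feeding standards; its maximum drives the post-processing
  threshold.

Readers never silently drop rows: every input row either becomes a valid
record or appears in the malformed-row report, and a file with zero valid
rows is a hard error.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["animal_id", "timestamp", "weight_kg", "concurrent_forage"]
REFERENCE_COLUMNS = ["animal_id", "date", "weight_kg"]
DAILY_COLUMNS = ["animal_id", "date", "weight_kg", "n_records"]
ESTIMATE_COLUMNS = ["animal_id", "window", "method", "estimate_kg", "n_days"]
ADG_COLUMNS = ["class_lower_kg", "adg_kg_per_day"]

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


class ReadError(ValueError):
    """Raised when a file yields no usable rows or violates a table invariant."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping from a user's CSV layout onto the canonical schema."""

    animal_id: str = "animal_id"
    timestamp: str = "timestamp"
    date: str = "date"
    weight: str = "weight_kg"
    concurrent_forage: str | None = "concurrent_forage"
    delimiter: str = ","


@dataclass(frozen=True)
class MalformedRow:
    """One rejected input row and the reason it was rejected."""

    index: int          # 0-based data-row index in the source file
    reason: str


@dataclass(frozen=True)
class MeasurementWindow:
    """A measurement campaign: ``length_days`` consecutive days with the
    static-scale reference taken on day ``mid_day_index`` (1-based).

    The study design this mirrors is one 7-day window per month with the
    reference weighing on the 4th day.
    """

    label: str
    start_date: datetime.date
    length_days: int = 7
    mid_day_index: int = 4

    def __post_init__(self) -> None:
        if self.length_days < 1:
            raise ValueError("length_days must be >= 1")
        if not 1 <= self.mid_day_index <= self.length_days:
            raise ValueError("mid_day_index must lie within the window")
        if isinstance(self.start_date, str):
            object.__setattr__(
                self, "start_date", datetime.date.fromisoformat(self.start_date)
            )

    @property
    def mid_date(self) -> datetime.date:
        return self.start_date + datetime.timedelta(days=self.mid_day_index - 1)

    @property
    def end_date(self) -> datetime.date:
        """Last day of the window (inclusive)."""
        return self.start_date + datetime.timedelta(days=self.length_days - 1)

    def day_index(self, date: datetime.date) -> int:
        """1-based day-of-window index of ``date``."""
        return (date - self.start_date).days + 1

    def contains(self, date: datetime.date) -> bool:
        return self.start_date <= date <= self.end_date


@dataclass(frozen=True)
class ADGTable:
    """Target average daily gain (kg/day) by live-weight class.

    ``entries`` is an ordered sequence of (weight-class lower bound kg,
    target ADG kg/day) with strictly increasing bounds and positive targets.
    """

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        entries = tuple((float(b), float(a)) for b, a in self.entries)
        if not entries:
            raise ValueError("ADG table must have at least one entry")
        bounds = [b for b, _ in entries]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("weight-class lower bounds must be strictly increasing")
        if any(a <= 0 for _, a in entries):
            raise ValueError("target ADG values must be positive")
        object.__setattr__(self, "entries", entries)

    @property
    def max_adg(self) -> float:
        return max(a for _, a in self.entries)

    def adg_for_weight(self, weight_kg: float) -> float:
        """Target ADG of the class containing ``weight_kg`` (lowest class if below all bounds)."""
        adg = self.entries[0][1]
        for bound, target in self.entries:
            if weight_kg >= bound:
                adg = target
        return adg


def _finish(
    df: pd.DataFrame, bad: list[MalformedRow], path: str | Path
) -> tuple[pd.DataFrame, list[MalformedRow]]:
    if len(df) == 0:
        raise ReadError(f"{path}: zero valid rows")
    return df.reset_index(drop=True), bad


def _parse_bool(raw: pd.Series) -> pd.Series:
    s = raw.astype(str).str.strip().str.lower()
    out = pd.Series(pd.NA, index=raw.index, dtype="object")
    out[s.isin(_TRUTHY)] = True
    out[s.isin(_FALSY) | raw.isna()] = False
    return out


def read_records(
    path: str | Path, dialect: Dialect = Dialect()
) -> tuple[pd.DataFrame, list[MalformedRow]]:
    """Read raw AWS weight records.

    Returns ``(records, malformed)`` where ``records`` has the canonical
    columns and ``malformed`` lists every rejected row with its reason.
    Row order is preserved.  Duplicate (animal, timestamp) rows are kept: an
    AWS legitimately emits many near-simultaneous readings per visit.
    """
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    for col in (dialect.animal_id, dialect.timestamp, dialect.weight):
        if col not in raw.columns:
            raise ReadError(f"{path}: missing mapped column {col!r}")

    animal = raw[dialect.animal_id].astype(str).str.strip()
    ts = pd.to_datetime(raw[dialect.timestamp], errors="coerce", format="ISO8601")
    weight = pd.to_numeric(raw[dialect.weight], errors="coerce")

    if dialect.concurrent_forage and dialect.concurrent_forage in raw.columns:
        flag = _parse_bool(raw[dialect.concurrent_forage])
    else:
        warnings.warn(
            f"{path}: no concurrent-forage column; flag defaults to False "
            "(initial screening becomes a no-op)",
            stacklevel=2,
        )
        flag = pd.Series(False, index=raw.index, dtype="object")

    bad: list[MalformedRow] = []
    ok = pd.Series(True, index=raw.index)
    for i in raw.index:
        reasons = []
        if not animal.iloc[i] or animal.iloc[i].lower() == "nan":
            reasons.append("empty animal_id")
        if pd.isna(ts.iloc[i]):
            reasons.append("unparseable timestamp")
        if pd.isna(weight.iloc[i]):
            reasons.append("unparseable weight")
        elif weight.iloc[i] <= 0:
            reasons.append("non-positive weight")
        if pd.isna(flag.iloc[i]):
            reasons.append("unparseable concurrent_forage flag")
        if reasons:
            bad.append(MalformedRow(int(i), "; ".join(reasons)))
            ok.iloc[i] = False

    df = pd.DataFrame(
        {
            "animal_id": animal[ok],
            "timestamp": ts[ok],
            "weight_kg": weight[ok].astype(float),
            "concurrent_forage": flag[ok].astype(bool),
        }
    )
    return _finish(df, bad, path)


def read_references(
    path: str | Path, dialect: Dialect = Dialect()
) -> tuple[pd.DataFrame, list[MalformedRow]]:
    """Read static-scale reference weights (one row per animal per campaign).

    A duplicated (animal, date) pair is an invariant violation and raises.
    """
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    for col in (dialect.animal_id, dialect.date, dialect.weight):
        if col not in raw.columns:
            raise ReadError(f"{path}: missing mapped column {col!r}")

    animal = raw[dialect.animal_id].astype(str).str.strip()
    date = pd.to_datetime(raw[dialect.date], errors="coerce", format="ISO8601")
    weight = pd.to_numeric(raw[dialect.weight], errors="coerce")

    bad: list[MalformedRow] = []
    ok = pd.Series(True, index=raw.index)
    for i in raw.index:
        reasons = []
        if not animal.iloc[i] or animal.iloc[i].lower() == "nan":
            reasons.append("empty animal_id")
        if pd.isna(date.iloc[i]):
            reasons.append("unparseable date")
        if pd.isna(weight.iloc[i]):
            reasons.append("unparseable weight")
        elif weight.iloc[i] <= 0:
            reasons.append("non-positive weight")
        if reasons:
            bad.append(MalformedRow(int(i), "; ".join(reasons)))
            ok.iloc[i] = False

    df = pd.DataFrame(
        {
            "animal_id": animal[ok],
            "date": date[ok].dt.date,
            "weight_kg": weight[ok].astype(float),
        }
    )
    dup = df.duplicated(subset=["animal_id", "date"])
    if dup.any():
        pair = df[dup].iloc[0]
        raise ReadError(
            f"{path}: duplicate reference for animal {pair.animal_id!r} on {pair.date}"
        )
    return _finish(df, bad, path)


def read_adg_table(path: str | Path) -> ADGTable:
    """Read a target-ADG-by-weight-class table (``class_lower_kg,adg_kg_per_day``)."""
    raw = pd.read_csv(path)
    for col in ADG_COLUMNS:
        if col not in raw.columns:
            raise ReadError(f"{path}: missing column {col!r}")
    return ADGTable(
        tuple(zip(raw["class_lower_kg"].astype(float), raw["adg_kg_per_day"].astype(float)))
    )


def read_table(path: str | Path, date_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    df = pd.read_csv(path)
    for col in date_columns:
        if col in df.columns:
            parsed = pd.to_datetime(df[col], format="ISO8601")
            df[col] = parsed.dt.date if (parsed.dt.time == datetime.time(0)).all() else parsed
    return df


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any domain table as CSV with a stable column order.

    Round-trip guarantee: ``read_table(path)`` returns value-identical data
    (weights to float64 precision, dates in ISO-8601).
    """
    rows.to_csv(path, index=False)


def windows_from_config(raw: Sequence[dict]) -> list[MeasurementWindow]:
    """Build windows from a list of mapping entries (e.g. parsed YAML)."""
    return [
        MeasurementWindow(
            label=str(w["label"]),
            start_date=datetime.date.fromisoformat(str(w["start_date"])),
            length_days=int(w.get("length_days", 7)),
            mid_day_index=int(w.get("mid_day_index", 4)),
        )
        for w in raw
    ]
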
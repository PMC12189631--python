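"""Stage 1 — screening, statistical outlier removal, daily averaging.

Raw AWS streams mix genuine weights with large contamination: residual feed
or manure on the platform adds tens of kg, and a partial stance (only some
hooves on the load cell) can subtract well over 100 kg.  Two classical,
parameter-light rules handle this:

* **Tukey's fences** — remove values outside ``[Q1 - k*IQR, Q3 + k*IQR]``
  (k = 1.5).  Quartiles are robust, so the rule tolerates heavy-tailed
  contamination well.
* **SD filter** — remove values more than ``k`` sample standard deviations
  from the mean (k = 1.5).  Mean and SD are themselves inflated by extreme
  values, so this rule loosens exactly when contamination is heaviest
  ("masking"); it is kept as the comparison alternative.

Both comparisons are inclusive: a value exactly on a fence/bound is kept.
Rules are applied independently within each (animal, window) group by
default; groups with fewer than ``min_group_size`` records pass through
unfiltered because quartiles and SDs of 2-3 points are meaningless.

After filtering, records are collapsed to per-animal per-calendar-day
means so that days with many feeder visits do not dominate the later
window statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MeasurementWindow

logger = logging.getLogger(__name__)

RULES = ("tukey", "sd")
GROUPINGS = ("animal_window", "animal_global")


@dataclass
class FilterResult:
    """Partition of the input records into kept and removed rows."""

    kept: pd.DataFrame
    removed: pd.DataFrame
    rule: str
    grouping: str
    n_small_groups: int = 0   # groups below min_group_size, passed through


def screen_concurrent(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records taken while the forage-intake system was active.

    Weight read while the adjacent forage system is in use is unreliable
    (shared platform / divided attention of the animal), so those rows are
    excluded before any statistics.  Order is preserved.
    """
    kept = records[~records["concurrent_forage"].astype(bool)]
    if len(kept) == 0 and len(records) > 0:
        logger.warning("screen_concurrent: all %d records flagged; nothing left", len(records))
    return kept


def tukey_fences(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Classify ``values`` against Tukey's fences ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Quartiles use linear interpolation of order statistics.  Boundary values
    are kept (removal requires strict exceedance).  Returns ``(kept,
    removed)`` preserving input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("tukey_fences: empty input")
    mask = tukey_mask(v, k)
    return v[mask], v[~mask]


def tukey_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def sd_filter(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Classify ``values`` against ``mean ± k * sample SD`` (n-1 denominator).

    A single value has an undefined SD; it is treated as 0 and the value is
    kept.  Boundary values are kept.  Returns ``(kept, removed)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("sd_filter: empty input")
    mask = sd_mask(v, k)
    return v[mask], v[~mask]


def sd_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    s = np.std(values, ddof=1) if values.size > 1 else 0.0
    return np.abs(values - np.mean(values)) <= k * s


_MASKS = {"tukey": tukey_mask, "sd": sd_mask}


def _window_labels(
    dates: pd.Series, windows: list[MeasurementWindow]
) -> pd.Series:
    labels = pd.Series(pd.NA, index=dates.index, dtype="object")
    for w in windows:
        inside = (dates >= w.start_date) & (dates <= w.end_date)
        labels[inside] = w.label
    return labels


def detect_outliers(
    records: pd.DataFrame,
    rule: str = "tukey",
    grouping: str = "animal_window",
    windows: list[MeasurementWindow] | None = None,
    k: float = 1.5,
    min_group_size: int = 4,
) -> FilterResult:
    """Apply an outlier rule independently within each group of records.

    ``grouping='animal_window'`` (default) groups by (animal, measurement
    window): robust statistics computed within one week of one animal's
    records, matching a design where each window is analysed on its own.
    ``'animal_global'`` pools each animal's records across all windows, for
    sensitivity analysis.

    Records falling outside every configured window cannot be assigned a
    group under ``animal_window``; they pass through unfiltered with a
    warning.  Groups smaller than ``min_group_size`` also pass through.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")

    records = records.copy()
    dates = records["timestamp"].dt.date
    if grouping == "animal_window":
        if windows is None:
            raise ValueError("grouping='animal_window' requires windows")
        records["_window"] = _window_labels(dates, windows)
        n_orphan = int(records["_window"].isna().sum())
        if n_orphan:
            logger.warning(
                "detect_outliers: %d records fall outside every window; passed through",
                n_orphan,
            )
        group_cols = ["animal_id", "_window"]
    else:
        records["_window"] = "all"
        group_cols = ["animal_id"]

    mask_fn = _MASKS[rule]
    keep = pd.Series(True, index=records.index)
    n_small = 0
    grouped = records[records["_window"].notna()].groupby(group_cols, sort=False)
    for _, grp in grouped:
        if len(grp) < min_group_size:
            n_small += 1
            logger.warning(
                "detect_outliers: group of %d records (< %d) passed through unfiltered",
                len(grp), min_group_size,
            )
            continue
        keep[grp.index] = mask_fn(grp["weight_kg"].to_numpy(), k)

    kept = records[keep].drop(columns="_window")
    removed = records[~keep].drop(columns="_window")
    return FilterResult(kept=kept, removed=removed, rule=rule,
                        grouping=grouping, n_small_groups=n_small)


def daily_average(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse records to one mean weight per (animal, calendar day).

    Calendar-day bucketing uses the timestamp's local date; no timezone
    arithmetic.  Returns columns ``animal_id, date, weight_kg, n_records``.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["animal_id", "date", "weight_kg", "n_records"])
    out = (
        records.assign(date=records["timestamp"].dt.date)
        .groupby(["animal_id", "date"], sort=True)["weight_kg"]
        .agg(weight_kg="mean", n_records="size")
        .reset_index()
    )
    out["n_records"] = out["n_records"].astype(int)
    return out
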
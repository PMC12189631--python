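"""Stage 3 — physiology-bounded correction of the daily weights.

Statistical filters only see the data's own spread; they cannot reject a
value that is *statistically* unremarkable but *biologically* impossible.
Stage 3 therefore bounds each daily weight by what a growing steer can
plausibly do in a month:

    threshold = max(target ADG over the weight classes) x 30 days

where the target average daily gain (ADG, kg/day) comes from a national
feeding-standard table supplied by the user.  A daily weight further than
``threshold`` kg from a per-animal baseline is removed, and the window
estimates are recomputed on the surviving days.  The factor of 30 covers a
full month of growth even though windows are only 7 days long, which keeps
the band generous enough not to over-filter.

The baseline anchoring the band is configurable:

* ``window_median`` (default) — the median of the animal's own daily
  weights in the current window.  Self-anchored: it needs no weighing
  history, so it is the only policy available in a deployment whose whole
  point is replacing routine static weighing, and because the anchor sits
  at the centre of the current data it can never trim clean
  measurements (the band is ~an order of magnitude wider than clean
  within-window variation).
* ``previous_reference`` — the animal's most recent static-scale weight
  before the window; the reading most literal about "bounded change
  relative to a known actual weight", but the anchor is up to a month
  stale, so a fast-growing animal consumes nearly the whole band and
  clean late-window days can be trimmed.  Falls back to ``window_median``
  when no earlier reference exists (e.g. first window).
* ``previous_estimate`` — the animal's accepted estimate from the
  preceding window (same fallback).

Band membership is inclusive: a value exactly at baseline ± threshold is
kept, consistent with the stage-1 convention.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ADGTable, MeasurementWindow

logger = logging.getLogger(__name__)

BASELINE_POLICIES = ("previous_reference", "previous_estimate", "window_median")


@dataclass(frozen=True)
class ThresholdSpec:
    """Maximum plausible |weight change| (kg) over ``factor_days`` days."""

    max_adg: float          # kg/day, maximum of the applicable ADG-table entries
    factor_days: float = 30.0
    threshold: float = None  # type: ignore[assignment]  # kg, derived

    def __post_init__(self) -> None:
        if self.threshold is None:
            object.__setattr__(self, "threshold", self.max_adg * self.factor_days)
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def adg_threshold(adg_table: ADGTable, factor_days: float = 30.0) -> ThresholdSpec:
    """Threshold = max over the ADG table of the target daily gain, x ``factor_days``."""
    return ThresholdSpec(max_adg=adg_table.max_adg, factor_days=float(factor_days))


def apply_threshold(
    daily: pd.DataFrame, baseline: float, spec: ThresholdSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition one animal-window's daily weights by the band
    ``[baseline - threshold, baseline + threshold]`` (inclusive)."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    dev = (daily["weight_kg"] - baseline).abs()
    keep = dev <= spec.threshold
    return daily[keep], daily[~keep]


def baseline_weight(
    animal_id: str,
    window: MeasurementWindow,
    references: pd.DataFrame | None = None,
    prior_estimates: pd.DataFrame | None = None,
    policy: str = "window_median",
    daily: pd.DataFrame | None = None,
    windows: list[MeasurementWindow] | None = None,
) -> float:
    """Baseline weight anchoring the plausibility band for one animal-window.

    ``daily`` (the animal's daily weights in the current window) is required
    for the ``window_median`` policy and for the fallback.  For
    ``previous_estimate``, ``prior_estimates`` must hold one estimate per
    (animal, window) — i.e. already narrowed to a single method — and
    ``windows`` supplies the window ordering.
    """
    if policy not in BASELINE_POLICIES:
        raise ValueError(f"unknown baseline policy {policy!r}")

    def _window_median() -> float:
        if daily is None or len(daily) == 0:
            raise ValueError(
                f"no data at all for animal {animal_id!r} in window {window.label!r}"
            )
        return float(np.median(daily["weight_kg"]))

    if policy == "window_median":
        return _window_median()

    if policy == "previous_reference":
        if references is not None:
            mine = references[
                (references["animal_id"] == animal_id)
                & (references["date"] < window.start_date)
            ]
            if len(mine):
                return float(mine.sort_values("date").iloc[-1]["weight_kg"])
        logger.info(
            "baseline_weight: no reference before window %r for %r; window_median fallback",
            window.label, animal_id,
        )
        return _window_median()

    # previous_estimate
    if prior_estimates is not None and windows is not None:
        earlier = [w for w in windows if w.end_date < window.start_date]
        if earlier:
            prev = max(earlier, key=lambda w: w.start_date)
            mine = prior_estimates[
                (prior_estimates["animal_id"] == animal_id)
                & (prior_estimates["window"] == prev.label)
            ]
            if len(mine) and np.isfinite(mine.iloc[0]["estimate_kg"]):
                return float(mine.iloc[0]["estimate_kg"])
    logger.info(
        "baseline_weight: no prior estimate before window %r for %r; window_median fallback",
        window.label, animal_id,
    )
    return _window_median()


def postprocess_daily(
    daily: pd.DataFrame,
    windows: list[MeasurementWindow],
    spec: ThresholdSpec,
    references: pd.DataFrame | None = None,
    policy: str = "window_median",
    prior_estimates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the plausibility band per (animal, window) across the dataset.

    Returns ``(kept, removed)`` daily weights; daily points outside every
    window are kept untouched.  Downstream, estimates are recomputed on the
    kept set (see :func:`awsproc.pipeline.run_pipeline`).
    """
    keep = pd.Series(True, index=daily.index)
    dates = daily["date"]
    for w in windows:
        in_w = (dates >= w.start_date) & (dates <= w.end_date)
        for animal in daily.loc[in_w, "animal_id"].unique():
            grp = daily[in_w & (daily["animal_id"] == animal)]
            base = baseline_weight(
                animal, w, references=references, prior_estimates=prior_estimates,
                policy=policy, daily=grp, windows=windows,
            )
            kept_g, removed_g = apply_threshold(grp, base, spec)
            if len(removed_g):
                logger.info(
                    "postprocess: removed %d daily points for %r in %r (baseline %.1f kg)",
                    len(removed_g), animal, w.label, base,
                )
            keep[removed_g.index] = False
    return daily[keep], daily[~keep]
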
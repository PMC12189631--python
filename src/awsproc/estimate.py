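"""Stage 2 — representative weight of each animal in each measurement window.

The static-scale reference is taken on the window's mid-date (day 4 of 7),
so each estimator reduces the window's daily weights to a single value to
be compared against that reference:

* ``mean`` / ``median`` of the daily weights (the mid-date's own daily
  value is included when present);
* ``linear_regression`` — ordinary least squares of daily weight on the
  1-based day-of-window index, fitted on every day EXCEPT the mid-date and
  evaluated at the mid-date index.  Holding out the mid-date keeps the
  prediction honest: the regression never sees the day it predicts.  The
  fit requires at least ``min_points`` (default 4) non-mid-date days;
  otherwise the estimate is missing (NaN).

On a perfectly linear trajectory all three agree with the true mid-date
weight, because the mid-date is the centre of the window: the mean and
median of a linear ramp over a symmetric window equal its central value.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import ESTIMATE_COLUMNS, MeasurementWindow

logger = logging.getLogger(__name__)

METHODS = ("mean", "median", "linear_regression")


def estimate_mean(daily: pd.DataFrame) -> tuple[float, int]:
    """Mean of the window's daily weights.  Returns ``(estimate, n_days)``;
    an empty window yields ``(nan, 0)``."""
    if len(daily) == 0:
        return math.nan, 0
    return float(np.mean(daily["weight_kg"])), len(daily)


def estimate_median(daily: pd.DataFrame) -> tuple[float, int]:
    """Median of the window's daily weights (even count: mean of the two
    central values)."""
    if len(daily) == 0:
        return math.nan, 0
    return float(np.median(daily["weight_kg"])), len(daily)


def estimate_linear(
    daily: pd.DataFrame,
    window: MeasurementWindow,
    min_points: int = 4,
) -> tuple[float, int]:
    """OLS prediction of the mid-date weight from the non-mid-date days.

    Fits weight ~ day-of-window index on all daily points except the
    mid-date, then evaluates the line at the mid-date index.  Returns
    ``(nan, n)`` when fewer than ``min_points`` days are available or the
    day indices are degenerate (all equal).
    """
    if len(daily) == 0:
        return math.nan, 0
    x = np.array([window.day_index(d) for d in daily["date"]], dtype=float)
    y = daily["weight_kg"].to_numpy(dtype=float)
    fit = x != window.mid_day_index
    x, y = x[fit], y[fit]
    n = int(fit.sum())
    if n < min_points:
        logger.info("estimate_linear: %d points < %d required; estimate missing", n, min_points)
        return math.nan, n
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        logger.warning("estimate_linear: zero predictor variance; estimate missing")
        return math.nan, n
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean()) - slope * float(x.mean())
    return intercept + slope * window.mid_day_index, n


def estimate_all(
    daily: pd.DataFrame,
    windows: list[MeasurementWindow],
    methods: tuple[str, ...] = METHODS,
    min_regression_points: int = 4,
) -> pd.DataFrame:
    """One estimate per (animal x window x method).

    Animals are taken as the union of animal ids in ``daily``; combinations
    with no usable data are emitted with a missing (NaN) estimate so the
    output layout is always the full cartesian product.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected subset of {METHODS}")
    animals = sorted(daily["animal_id"].unique()) if len(daily) else []
    rows = []
    for animal in animals:
        mine = daily[daily["animal_id"] == animal]
        for w in windows:
            inside = mine[[w.contains(d) for d in mine["date"]]]
            for method in methods:
                if method == "mean":
                    est, n = estimate_mean(inside)
                elif method == "median":
                    est, n = estimate_median(inside)
                else:
                    est, n = estimate_linear(inside, w, min_regression_points)
                rows.append((animal, w.label, method, est, n))
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
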
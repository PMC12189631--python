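"""Accuracy metrics and the multi-method statistical comparison battery.

Accuracy of a (filter rule x estimator) combination against the
static-scale references is summarised by

* RMSE (kg) of the paired estimate/reference differences,
* the mean absolute difference (kg), and
* the margin-of-error ratio: the percentage of animals whose estimate is
  within 5% (resp. 10%) of their reference weight, boundaries inclusive.

The comparison battery mirrors a conventional analysis plan for "do the
automated estimates differ from the scale?":

1. pairwise two-sided variance-ratio F-tests of each method group against
   the reference group (homogeneity of variances);
2. Dunnett's many-to-one test of each method against the reference;
3. Tukey's HSD for all pairwise method comparisons;
4. a non-parametric arm — Kruskal-Wallis followed by Dunn's post-hoc
   test — run on per-animal paired differences (estimate - reference), so
   that between-animal weight variation (the "ID effect") is removed by
   the pairing rather than modelled.

Dunnett, Tukey HSD and Kruskal-Wallis are delegated to scipy; Dunn's
rank-based z-tests (with tie correction and Holm adjustment by default)
are implemented here.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MeasurementWindow

MARGINS = (5.0, 10.0)


# ---------------------------------------------------------------- metrics

def rmse(pairs: Sequence[tuple[float, float]]) -> float:
    """Root mean square error of (estimate, reference) pairs, in kg."""
    est, ref = _split(pairs)
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def mean_abs_diff(pairs: Sequence[tuple[float, float]]) -> float:
    est, ref = _split(pairs)
    return float(np.mean(np.abs(est - ref)))


def margin_ratio(pairs: Sequence[tuple[float, float]], pct: float) -> float:
    """Percentage of pairs with relative error |est - ref| / ref <= pct/100.

    The boundary is inclusive (an error of exactly pct% counts as inside);
    the denominator is the reference weight.
    """
    est, ref = _split(pairs)
    if np.any(ref <= 0):
        raise ValueError("margin_ratio: non-positive reference weight")
    inside = np.abs(est - ref) / ref <= pct / 100.0
    return float(100.0 * np.mean(inside))


def _split(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty pairs")
    return arr[:, 0], arr[:, 1]


# ------------------------------------------------------------- test battery

def variance_homogeneity(
    groups: Mapping[str, Sequence[float]], reference: str
) -> pd.DataFrame:
    """Two-sided variance-ratio F-test of each group against ``reference``.

    F = s2_group / s2_reference with (n_g - 1, n_ref - 1) degrees of
    freedom; the two-sided p doubles the smaller tail.
    """
    ref = np.asarray(groups[reference], dtype=float)
    if ref.size < 2:
        raise ValueError("variance_homogeneity: reference group needs n >= 2")
    rows = []
    for name, values in groups.items():
        if name == reference:
            continue
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"variance_homogeneity: group {name!r} needs n >= 2")
        f = np.var(v, ddof=1) / np.var(ref, ddof=1)
        dfn, dfd = v.size - 1, ref.size - 1
        p = 2.0 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
        rows.append((name, float(f), dfn, dfd, float(min(p, 1.0))))
    return pd.DataFrame(rows, columns=["group", "F", "df_num", "df_den", "p"])


def dunnett_vs_reference(
    groups: Mapping[str, Sequence[float]], reference: str
) -> pd.DataFrame:
    """Dunnett's many-to-one comparison of every group against ``reference``
    (two-sided, multiplicity-adjusted p-values)."""
    names = [n for n in groups if n != reference]
    if not names:
        raise ValueError("dunnett_vs_reference: no treatment groups")
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} absent")
    pooled = np.concatenate([np.asarray(groups[n], dtype=float) for n in groups])
    if np.ptp(pooled) == 0.0:
        # identical constant groups: zero variance, no differences to reject
        return pd.DataFrame(
            {"group": names, "statistic": 0.0, "p_adjusted": 1.0}
        )
    res = stats.dunnett(
        *(np.asarray(groups[n], dtype=float) for n in names),
        control=np.asarray(groups[reference], dtype=float),
    )
    return pd.DataFrame(
        {"group": names, "statistic": res.statistic, "p_adjusted": res.pvalue}
    )


def tukey_hsd_test(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey's HSD over all group pairs (studentized-range adjustment)."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("tukey_hsd_test: need >= 2 groups")
    res = stats.tukey_hsd(*(np.asarray(groups[n], dtype=float) for n in names))
    rows = [
        (a, b, float(res.statistic[i, j]), float(res.pvalue[i, j]))
        for (i, a), (j, b) in itertools.combinations(enumerate(names), 2)
    ]
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adjusted"])


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], p_adjust: str = "holm"
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus H (tie-corrected) plus Dunn's post-hoc z-tests.

    Dunn's statistic for groups i, j on the pooled mid-ranks:

        z = (rbar_i - rbar_j) / sqrt([N(N+1)/12 - T] * (1/n_i + 1/n_j))

    with tie term T = sum(t^3 - t) / [12 (N - 1)] over tie groups.  Raw
    two-sided p-values are adjusted by ``p_adjust`` (holm, bonferroni, or
    none).  When every observation across all groups is identical, H is
    defined as 0 with p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("kruskal_dunn: need >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = stats.kruskal(*arrays)

    ranks = stats.rankdata(pooled)
    n_tot = pooled.size
    sizes = np.array([a.size for a in arrays])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(names))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(min(p_raw, 1.0))))
    dunn = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if p_adjust == "none" or len(dunn) == 0:
        dunn["p_adjusted"] = dunn["p_raw"]
    else:
        dunn["p_adjusted"] = multipletests(dunn["p_raw"].to_numpy(), method=p_adjust)[1]
    return float(h), float(p_omni), dunn


# ------------------------------------------------------------------ report

def _metric_row(pairs: np.ndarray) -> dict:
    est, ref = pairs[:, 0], pairs[:, 1]
    return {
        "n": int(len(pairs)),
        "predicted_mean": float(np.mean(est)),
        "predicted_sd": float(np.std(est, ddof=1)) if len(est) > 1 else 0.0,
        "reference_mean": float(np.mean(ref)),
        "reference_sd": float(np.std(ref, ddof=1)) if len(ref) > 1 else 0.0,
        "rmse": rmse(pairs),
        "mean_abs_diff": mean_abs_diff(pairs),
        "pct_within_5": margin_ratio(pairs, 5.0),
        "pct_within_10": margin_ratio(pairs, 10.0),
    }


def join_pairs(
    estimates: pd.DataFrame,
    references: pd.DataFrame,
    windows: list[MeasurementWindow],
) -> pd.DataFrame:
    """Join estimates to the reference taken at each window's mid-date.

    Missing estimates (NaN) are retained with ``paired=False`` so exclusion
    counts can be reported; estimates with no matching reference are
    dropped.
    """
    mid = pd.DataFrame(
        {"window": [w.label for w in windows], "date": [w.mid_date for w in windows]}
    )
    ref = references.merge(mid, on="date")[["animal_id", "window", "weight_kg"]]
    ref = ref.rename(columns={"weight_kg": "reference_kg"})
    out = estimates.merge(ref, on=["animal_id", "window"], how="inner")
    out["paired"] = np.isfinite(out["estimate_kg"])
    return out


def build_report(
    estimates: pd.DataFrame,
    references: pd.DataFrame,
    windows: list[MeasurementWindow],
    alpha: float = 0.05,
    dunn_adjust: str = "holm",
) -> tuple[pd.DataFrame, dict]:
    """Score every combination per window and pooled, and run the battery.

    ``estimates`` must carry ``animal_id, window, method, estimate_kg`` and
    may carry ``rule`` (filter rule) and ``post`` (bool, post-processing
    applied) columns; combinations are formed from whichever of those are
    present.  Returns ``(report, battery)`` where ``report`` has one row
    per combination per window plus a pooled "Total" row, and ``battery``
    is a JSON-serializable dict keyed by combination and scope.
    """
    joined = join_pairs(estimates, references, windows)
    if not joined["paired"].any():
        raise ValueError("build_report: no joinable (estimate, reference) pairs")

    combo_cols = [c for c in ("rule", "post") if c in joined.columns]
    scopes = [w.label for w in windows] + ["Total"]
    rows = []
    for key, grp in joined.groupby(combo_cols + ["method"], sort=False, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        base = dict(zip(combo_cols + ["method"], key))
        for scope in scopes:
            sub = grp if scope == "Total" else grp[grp["window"] == scope]
            paired = sub[sub["paired"]]
            row = dict(base, window=scope, n_excluded=int((~sub["paired"]).sum()))
            if len(paired):
                row.update(_metric_row(paired[["estimate_kg", "reference_kg"]].to_numpy()))
            else:
                row.update({"n": 0})
            rows.append(row)
    report = pd.DataFrame(rows)

    battery = {"alpha": alpha}
    combos = joined.groupby(combo_cols, dropna=False) if combo_cols else [((), joined)]
    for key, grp in combos:
        key = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key) if combo_cols else "all"
        battery[label] = {
            scope: _battery_for(
                grp if scope == "Total" else grp[grp["window"] == scope], dunn_adjust
            )
            for scope in scopes
        }
    return report, battery


def _battery_for(joined: pd.DataFrame, dunn_adjust: str) -> dict:
    """Battery on one combination: method groups vs the reference group."""
    paired = joined[joined["paired"]]
    methods = [m for m in paired["method"].unique()]
    if len(paired) == 0 or not methods:
        return {"skipped": "no paired data"}
    groups = {"reference": paired[paired["method"] == methods[0]]["reference_kg"].to_numpy()}
    for m in methods:
        groups[m] = paired[paired["method"] == m]["estimate_kg"].to_numpy()
    if any(len(v) < 2 for v in groups.values()):
        return {"skipped": "a group has n < 2"}

    # paired differences per method for the non-parametric arm (ID effect
    # removed by pairing)
    diffs = {
        m: (paired.loc[paired["method"] == m, "estimate_kg"].to_numpy()
            - paired.loc[paired["method"] == m, "reference_kg"].to_numpy())
        for m in methods
    }
    out = {
        "f_test": variance_homogeneity(groups, "reference").to_dict("records"),
        "dunnett": dunnett_vs_reference(groups, "reference").to_dict("records"),
        "tukey_hsd": tukey_hsd_test(groups).to_dict("records"),
    }
    if len(diffs) >= 2:
        h, p, dunn = kruskal_dunn(diffs, p_adjust=dunn_adjust)
        out["kruskal_wallis"] = {"H": h, "p": p}
        out["dunn"] = dunn.to_dict("records")
    return out
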
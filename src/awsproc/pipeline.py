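"""End-to-end orchestration: screen -> filter -> daily-average -> estimate
-> post-process -> re-estimate -> evaluate.

A run executes every requested (filter rule x estimator) combination, each
both without and with stage-3 post-processing, so the before/after
contrast is a first-class output rather than two separate runs.  All
intermediate partitions (screened, filtered-out, post-processed-out
records) are written as audit CSVs, and a run log captures the config
hash, library versions and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimate as est_mod
from . import evaluate as eval_mod
from . import postprocess as post_mod
from . import preprocess as pre_mod
from .io import (
    ADGTable,
    MeasurementWindow,
    read_adg_table,
    read_records,
    read_references,
    windows_from_config,
    write_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully describes one pipeline run (parsed from run.yaml)."""

    records_path: str
    references_path: str
    output_dir: str
    windows: list[MeasurementWindow]
    adg_table_path: str | None = None
    rules: tuple[str, ...] = ("tukey", "sd")
    k: float = 1.5
    grouping: str = "animal_window"
    min_group_size: int = 4
    methods: tuple[str, ...] = est_mod.METHODS
    min_regression_points: int = 4
    postprocess_enabled: bool = True
    baseline_policy: str = "window_median"
    factor_days: float = 30.0
    alpha: float = 0.05
    dunn_adjust: str = "holm"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        paths = raw.get("paths", {})
        pre = raw.get("preprocess", {})
        est = raw.get("estimate", {})
        post = raw.get("postprocess", {})
        ev = raw.get("evaluate", {})
        rules = pre.get("rule", ["tukey", "sd"])
        if isinstance(rules, str):
            rules = [rules]
        methods = est.get("methods", list(est_mod.METHODS))
        if isinstance(methods, str):
            methods = [methods]
        return cls(
            records_path=paths["records"],
            references_path=paths["references"],
            adg_table_path=paths.get("adg_table"),
            output_dir=paths.get("output_dir", "."),
            windows=windows_from_config(raw["windows"]),
            rules=tuple(rules),
            k=float(pre.get("k", 1.5)),
            grouping=pre.get("grouping", "animal_window"),
            min_group_size=int(pre.get("min_group_size", 4)),
            methods=tuple(methods),
            min_regression_points=int(est.get("min_regression_points", 4)),
            postprocess_enabled=bool(post.get("enabled", True)),
            baseline_policy=post.get("baseline_policy", "window_median"),
            factor_days=float(post.get("factor_days", 30.0)),
            alpha=float(ev.get("alpha", 0.05)),
            dunn_adjust=ev.get("dunn_adjust", "holm"),
        )


@dataclass
class PipelineResult:
    estimates: pd.DataFrame          # all combos; columns incl. rule, post
    report: pd.DataFrame
    battery: dict
    ranking: pd.DataFrame
    counts: dict                     # per-stage record counts (audit trail)
    daily: dict                      # (rule, post) -> daily weights used
    removed: dict                    # stage label -> removed records/days


def run_study(
    records: pd.DataFrame,
    references: pd.DataFrame,
    windows: list[MeasurementWindow],
    adg_table: ADGTable | None = None,
    rules: tuple[str, ...] = ("tukey", "sd"),
    methods: tuple[str, ...] = est_mod.METHODS,
    k: float = 1.5,
    grouping: str = "animal_window",
    min_group_size: int = 4,
    min_regression_points: int = 4,
    postprocess_enabled: bool = True,
    baseline_policy: str = "window_median",
    factor_days: float = 30.0,
    alpha: float = 0.05,
    dunn_adjust: str = "holm",
) -> PipelineResult:
    """In-memory pipeline over already-loaded tables.

    Stage 2 estimates are computed on the filtered daily weights; when
    post-processing is enabled the daily weights are additionally bounded
    by the ADG band and the estimates recomputed on the surviving days
    (``post=True`` rows).  Stage-2 rows are never mutated: disabling
    post-processing reproduces them exactly.
    """
    if postprocess_enabled and adg_table is None:
        raise PipelineError(
            "postprocess",
            "post-processing is enabled but no ADG table was provided; "
            "supply paths.adg_table (CSV: class_lower_kg,adg_kg_per_day) "
            "or set postprocess.enabled: false",
        )

    counts = {"input_records": int(len(records))}
    screened = pre_mod.screen_concurrent(records)
    counts["after_screening"] = int(len(screened))
    if len(screened) == 0:
        raise PipelineError("preprocess", "no records left after concurrent-forage screening")

    estimates = []
    daily_sets: dict = {}
    removed: dict = {}
    spec = post_mod.adg_threshold(adg_table, factor_days) if postprocess_enabled else None

    for rule in rules:
        fr = pre_mod.detect_outliers(
            screened, rule=rule, grouping=grouping, windows=windows,
            k=k, min_group_size=min_group_size,
        )
        removed[f"filter_{rule}"] = fr.removed
        counts[f"outliers_removed_{rule}"] = int(len(fr.removed))
        daily = pre_mod.daily_average(fr.kept)
        counts[f"daily_points_{rule}"] = int(len(daily))
        daily_sets[(rule, False)] = daily

        stage2 = est_mod.estimate_all(daily, windows, methods, min_regression_points)
        stage2.insert(0, "rule", rule)
        stage2.insert(1, "post", False)
        estimates.append(stage2)

        if postprocess_enabled:
            prior = None
            if baseline_policy == "previous_estimate":
                # anchor on the stage-2 mean estimate of the preceding window
                prior = stage2[stage2["method"] == "mean"][
                    ["animal_id", "window", "estimate_kg"]
                ]
            kept_daily, removed_daily = post_mod.postprocess_daily(
                daily, windows, spec, references=references,
                policy=baseline_policy, prior_estimates=prior,
            )
            removed[f"post_{rule}"] = removed_daily
            counts[f"post_removed_daily_{rule}"] = int(len(removed_daily))
            counts[f"daily_points_{rule}_post"] = int(len(kept_daily))
            daily_sets[(rule, True)] = kept_daily
            stage3 = est_mod.estimate_all(kept_daily, windows, methods, min_regression_points)
            stage3.insert(0, "rule", rule)
            stage3.insert(1, "post", True)
            estimates.append(stage3)

    all_estimates = pd.concat(estimates, ignore_index=True)
    try:
        report, battery = eval_mod.build_report(
            all_estimates, references, windows, alpha=alpha, dunn_adjust=dunn_adjust
        )
    except ValueError as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    ranking = compare_configurations([report])
    return PipelineResult(
        estimates=all_estimates, report=report, battery=battery,
        ranking=ranking, counts=counts, daily=daily_sets, removed=removed,
    )


def compare_configurations(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Rank combinations by pooled ("Total") RMSE; ties broken by the 5%
    margin ratio, higher first."""
    if not reports:
        raise ValueError("compare_configurations: no reports")
    window_sets = [set(r["window"]) for r in reports]
    shared = set.intersection(*window_sets)
    if "Total" not in shared:
        raise ValueError("compare_configurations: reports have disjoint window sets")
    pooled = pd.concat(reports, ignore_index=True)
    pooled = pooled[(pooled["window"] == "Total") & pooled["rmse"].notna()]
    ranking = pooled.sort_values(
        ["rmse", "pct_within_5"], ascending=[True, False]
    ).reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    return ranking


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based pipeline run: read inputs, execute, write all artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        records, bad_records = read_records(config.records_path)
        references, bad_refs = read_references(config.references_path)
    except (OSError, ValueError) as exc:
        raise PipelineError("read", str(exc)) from exc
    adg_table = None
    if config.postprocess_enabled:
        if config.adg_table_path is None:
            raise PipelineError(
                "read",
                "postprocess.enabled is true but paths.adg_table is missing; "
                "provide the target-ADG table CSV or disable post-processing",
            )
        try:
            adg_table = read_adg_table(config.adg_table_path)
        except (OSError, ValueError) as exc:
            raise PipelineError("read", str(exc)) from exc

    result = run_study(
        records, references, config.windows, adg_table,
        rules=config.rules, methods=config.methods, k=config.k,
        grouping=config.grouping, min_group_size=config.min_group_size,
        min_regression_points=config.min_regression_points,
        postprocess_enabled=config.postprocess_enabled,
        baseline_policy=config.baseline_policy, factor_days=config.factor_days,
        alpha=config.alpha, dunn_adjust=config.dunn_adjust,
    )
    result.counts["malformed_record_rows"] = len(bad_records)
    result.counts["malformed_reference_rows"] = len(bad_refs)

    write_table(result.estimates, outdir / "estimates.csv")
    write_table(result.report, outdir / "report.csv")
    write_table(result.ranking, outdir / "ranking.csv")
    for stage, df in result.removed.items():
        write_table(df, outdir / f"removed_{stage}.csv")
    with open(outdir / "battery.json", "w") as fh:
        json.dump(result.battery, fh, indent=2, default=str)
    log = {
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "versions": _versions(),
        "counts": result.counts,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return result


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
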
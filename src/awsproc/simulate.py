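"""Synthetic herd + automated-weighing-system (AWS) stream generator.

The study design this emulates: three dozen growing steers, each visiting a
load-cell feeder station several times a day during one 7-day window per
month, with a static-scale reference weighing on each window's mid-date
(day 4).  The generator provides a known ground truth so the full pipeline
is testable end to end:

* **Trajectories** — per-animal linear growth ``w(t) = w0 + ADG * t`` with
  ``w0 ~ N(initial_weight_mean, sd)`` and per-animal ADG drawn from a
  normal truncated at +/-2 sd (unbounded Gaussian tails would produce
  unphysiological growth rates).  Linear growth is adequate at the 3-month
  scale, and it is exactly the assumption the stage-3 ADG band encodes.
* **Visits** — a fixed ``round(visits_per_day_mean)`` records per window
  day per animal, at random times of day, each the day's true weight plus
  ``N(0, noise_sd)`` platform noise.  The daily visit count is kept
  deterministic so that the clean-data limit is an exact fixed point of
  both outlier rules; the pipeline only consumes daily averages, so visit
  count randomness adds nothing downstream (see docs/methods.md).
* **Contamination** — each record is independently corrupted with
  probability ``contamination_rate``: half receive a positive offset
  ``+U(positive_offset_range)`` (residual feed/manure on the platform),
  half a large negative offset ``-U(negative_offset_range)`` (partial
  stance on the load cell).  The two-sided, asymmetric heavy-tailed mix is
  what separates a robust (quartile-based) filter from a mean/SD one.

Everything is deterministic given (config, seed): identical inputs give
byte-identical output CSVs.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ADGTable, MeasurementWindow, write_table


def default_windows() -> list[MeasurementWindow]:
    """Three 7-day mid-month windows (Feb-Apr 2019), mid-date on day 4."""
    return [
        MeasurementWindow("Feb", datetime.date(2019, 2, 11)),
        MeasurementWindow("Mar", datetime.date(2019, 3, 11)),
        MeasurementWindow("Apr", datetime.date(2019, 4, 8)),
    ]


#: Example target-ADG table by weight class (kg -> kg/day).  SYNTHETIC:
#: plausible magnitudes for growing beef steers, standing in for a national
#: feeding-standard table the user would normally supply.
EXAMPLE_ADG_TABLE = ADGTable(
    entries=((200.0, 0.90), (250.0, 1.00), (300.0, 1.10), (350.0, 1.15), (400.0, 1.20))
)


@dataclass(frozen=True)
class SimConfig:
    """Herd and measurement-process parameters (defaults match the emulated
    study design: 36 steers, 3 monthly 7-day windows, ~330 kg starting
    weight)."""

    n_animals: int = 36
    windows: tuple[MeasurementWindow, ...] = field(
        default_factory=lambda: tuple(default_windows())
    )
    initial_weight_mean: float = 330.0   # kg at the first window's first day
    initial_weight_sd: float = 20.0
    adg_mean: float = 0.8                # kg/day
    adg_sd: float = 0.15                 # truncated at +/-2 sd
    visits_per_day_mean: float = 4.0     # records per animal per window day
    noise_sd: float = 5.0                # kg, platform measurement noise
    contamination_rate: float = 0.05     # per-record corruption probability
    positive_offset_range: tuple[float, float] = (20.0, 80.0)
    negative_offset_range: tuple[float, float] = (60.0, 200.0)
    reference_noise_sd: float = 0.0      # static scale treated as exact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        for name in ("initial_weight_sd", "adg_sd", "noise_sd", "reference_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.visits_per_day_mean < 0:
            raise ValueError("visits_per_day_mean must be >= 0")
        if not self.windows:
            raise ValueError("at least one measurement window required")


@dataclass
class GroundTruth:
    """Simulator bookkeeping: per-animal growth parameters and the true
    weight at every window mid-date."""

    animals: pd.DataFrame      # animal_id, initial_weight_kg, adg_kg_per_day
    mid_weights: pd.DataFrame  # animal_id, window, date, true_weight_kg
    t0: datetime.date          # day 0 of the growth model

    def true_weight(self, animal_id: str, date: datetime.date) -> float:
        row = self.animals[self.animals["animal_id"] == animal_id].iloc[0]
        days = (date - self.t0).days
        return float(row["initial_weight_kg"] + row["adg_kg_per_day"] * days)


def _animal_ids(n: int) -> list[str]:
    return [f"steer{i:03d}" for i in range(1, n + 1)]


def simulate_trajectories(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Draw per-animal growth lines and tabulate true mid-date weights."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = _animal_ids(config.n_animals)
    w0 = rng.normal(config.initial_weight_mean, config.initial_weight_sd, config.n_animals)
    if config.adg_sd > 0:
        adg = stats.truncnorm.rvs(
            -2.0, 2.0, loc=config.adg_mean, scale=config.adg_sd,
            size=config.n_animals, random_state=rng,
        )
    else:
        adg = np.full(config.n_animals, config.adg_mean)
    animals = pd.DataFrame(
        {"animal_id": ids, "initial_weight_kg": w0, "adg_kg_per_day": adg}
    )
    t0 = min(w.start_date for w in config.windows)
    rows = [
        (a, w.label, w.mid_date, w0[i] + adg[i] * (w.mid_date - t0).days)
        for i, a in enumerate(ids)
        for w in config.windows
    ]
    mid = pd.DataFrame(rows, columns=["animal_id", "window", "date", "true_weight_kg"])
    return GroundTruth(animals=animals, mid_weights=mid, t0=t0)


def simulate_visits(
    truth: GroundTruth, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit clean AWS records and static-scale references.

    Records carry the bookkeeping columns ``true_weight_kg`` and
    ``contaminated`` (all False here); drop them before feeding files to a
    consumer that should not see ground truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    visits = int(round(config.visits_per_day_mean))
    rows = []
    for i, animal in enumerate(truth.animals["animal_id"]):
        w0 = truth.animals["initial_weight_kg"].iloc[i]
        adg = truth.animals["adg_kg_per_day"].iloc[i]
        for w in config.windows:
            for d in range(w.length_days):
                date = w.start_date + datetime.timedelta(days=d)
                true_w = w0 + adg * (date - truth.t0).days
                if visits == 0:
                    continue
                # visit times: uniform over the feeding day (06:00-22:00)
                secs = np.sort(rng.integers(6 * 3600, 22 * 3600, size=visits))
                noise = rng.normal(0.0, config.noise_sd, size=visits) if config.noise_sd > 0 else np.zeros(visits)
                for s, eps in zip(secs, noise):
                    ts = datetime.datetime.combine(date, datetime.time()) + datetime.timedelta(seconds=int(s))
                    rows.append((animal, ts, true_w + eps, False, true_w, False))
    records = pd.DataFrame(
        rows,
        columns=["animal_id", "timestamp", "weight_kg", "concurrent_forage",
                 "true_weight_kg", "contaminated"],
    )
    if len(records):
        records["timestamp"] = pd.to_datetime(records["timestamp"])

    refs = truth.mid_weights.copy()
    if config.reference_noise_sd > 0:
        refs["true_weight_kg"] = refs["true_weight_kg"] + rng.normal(
            0.0, config.reference_noise_sd, len(refs)
        )
    references = refs.rename(columns={"true_weight_kg": "weight_kg"})[
        ["animal_id", "date", "weight_kg"]
    ].reset_index(drop=True)
    return records, references


def contaminate(
    records: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Independently corrupt each record with probability ``contamination_rate``.

    Corrupted records get ``+U(positive_offset_range)`` or
    ``-U(negative_offset_range)`` with equal probability; the
    ``contaminated`` flag is set so detector recall/precision can be scored
    against ground truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = records.copy()
    n = len(out)
    if n == 0 or config.contamination_rate == 0.0:
        return out
    hit = rng.random(n) < config.contamination_rate
    positive = rng.random(n) < 0.5
    lo_p, hi_p = config.positive_offset_range
    lo_n, hi_n = config.negative_offset_range
    offsets = np.where(
        positive, rng.uniform(lo_p, hi_p, n), -rng.uniform(lo_n, hi_n, n)
    )
    out.loc[hit, "weight_kg"] = out.loc[hit, "weight_kg"] + offsets[hit]
    out.loc[hit, "contaminated"] = True
    return out


@dataclass
class SimResult:
    records: pd.DataFrame       # incl. true_weight_kg / contaminated bookkeeping
    references: pd.DataFrame
    truth: GroundTruth
    config: SimConfig

    @property
    def public_records(self) -> pd.DataFrame:
        """Records as an AWS would emit them (no ground-truth columns)."""
        return self.records[["animal_id", "timestamp", "weight_kg", "concurrent_forage"]]


def simulate(config: SimConfig, seed: int | None = None) -> SimResult:
    """Full generator: trajectories -> visits -> contamination."""
    if seed is not None:
        config = replace(config, seed=seed)
    master = np.random.default_rng(config.seed)
    s_traj, s_vis, s_cont = (int(x) for x in master.integers(0, 2**31 - 1, 3))
    truth = simulate_trajectories(config, seed=s_traj)
    records, references = simulate_visits(truth, config, seed=s_vis)
    records = contaminate(records, config, seed=s_cont)
    return SimResult(records=records, references=references, truth=truth, config=config)


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write records.csv, references.csv and ground_truth.csv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "references": outdir / "references.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    write_table(result.public_records, paths["records"])
    write_table(result.references, paths["references"])
    truth = result.truth.mid_weights.merge(result.truth.animals, on="animal_id")
    write_table(truth, paths["ground_truth"])
    return paths
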
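# awsproc

Turning noisy automated-weighing-system (AWS) records into reliable cattle
body weights.

An AWS is a load-cell platform at a feeder station that logs an animal's
weight (via its RFID tag) at every visit. It replaces stressful manual
weighing and yields rich time series — but the raw stream is badly
contaminated: residual feed or manure on the platform inflates readings by
tens of kg, and an animal standing half-off the cell can cut a reading by
100 kg or more. `awsproc` implements a three-stage processing algorithm
that converts this stream into one trustworthy weight per animal per
measurement window, plus the evaluation machinery to quantify how well it
does so against static-scale reference weighings.

**Who it is for:** precision-livestock researchers and farm-systems
engineers who have (a) an AWS record stream and (b) occasional static-scale
reference weights, and want per-animal weight estimates with a defensible
error budget.

## The algorithm

Measurements are organised in 7-day windows (e.g. one week per month) with
the reference weighing on the window's mid-date (day 4).

1. **Pre-processing.** Records taken while a concurrent forage-intake
   system was active are screened out. Within each (animal, window) group,
   outliers are removed by one of two rules — Tukey's fences
   (keep `Q1 − 1.5·IQR ≤ w ≤ Q3 + 1.5·IQR`) or an SD filter
   (keep `|w − w̄| ≤ 1.5·s`) — and the survivors are collapsed to one mean
   weight per animal per calendar day.
2. **Estimation.** Each animal-window's daily weights are reduced to a
   representative weight by the *mean*, the *median*, or a *linear
   regression* of weight on day-of-window fitted on all days except the
   mid-date and evaluated at the mid-date (requires ≥ 4 non-mid-date
   days).
3. **Post-processing.** A physiological plausibility band bounds each daily
   weight: `threshold = max(ADG_BW) × 30` kg, where `ADG_BW` is the target
   average daily gain (kg/day) by weight class from a national
   feeding-standard table. Daily weights outside `baseline ± threshold`
   are removed and estimates recomputed; the baseline defaults to the
   window's own daily-weight median.

Accuracy against the references is reported as RMSE (kg) and the
percentage of animals within 5% / 10% of their reference weight, and a
statistical battery (pairwise F-tests, Dunnett vs. reference, Tukey HSD,
Kruskal–Wallis + Dunn on paired differences) tests whether the automated
estimates differ from the scale.

## Worked example

No AWS dataset ships with the package; the built-in simulator generates a
realistic herd with known ground truth (36 steers growing ~0.8 kg/day from
~330 kg, 4 visits/day over three monthly windows, 5 kg platform noise, 5%
heavy-tailed contamination):

```bash
awsproc simulate -o data/ --seed 1
awsproc run -c run.yaml
```

with `run.yaml`:

```yaml
paths:
  records: data/records.csv
  references: data/references.csv
  adg_table: adg.csv          # class_lower_kg,adg_kg_per_day
  output_dir: out/
windows:
  - {label: Feb, start_date: 2019-02-11}
  - {label: Mar, start_date: 2019-03-11}
  - {label: Apr, start_date: 2019-04-08}
```

The run prints

```
reports written to out/
best combination: rule=tukey method=mean post=False (RMSE 1.11 kg, 100.0% within 5%)
```

and `out/report.csv` contains, per combination, the pooled rows (seed 1):

| rule  | post  | method | RMSE (kg) | % within 5% |
|-------|-------|--------|-----------|-------------|
| tukey | True  | mean   | 1.11      | 100.0       |
| tukey | True  | median | 1.44      | 100.0       |
| sd    | True  | mean   | 1.42      | 100.0       |

Reading these numbers: of 3024 simulated records, Tukey's fences removed
211 (nearly all of the injected contamination) while the SD filter removed
239 but let more large offsets through by inflating its own spread
estimate — hence the mean estimator paired with Tukey's fences gives the
lowest pooled RMSE, and post-processing can only tighten results further
(here the Tukey branch was already clean, so its post rows tie). The
simulator's remaining 1.1 kg RMSE is the irreducible effect of 5 kg visit
noise averaged over ~4 visits × 7 days.

`out/battery.json` holds the statistical battery; with unbiased noise no
method differs significantly from the reference (all p > 0.05), which is
exactly what a well-calibrated pipeline should report.

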
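# Methods

## Problem setting and model

An automated weighing system (AWS) records a growing steer's weight at
every feeder visit. Over a 7-day measurement window the animal's true
weight is very nearly linear in time (`w(t) = w0 + ADG·t`, with average
daily gain ADG ≈ 0.5–1.1 kg/day for growing beef steers), while the
record stream adds two error components: zero-mean platform noise of a
few kg, and sparse gross contamination — positive offsets from residual
feed/manure on the platform, and large negative readings from a partial
stance on the load cell. The pipeline's premise is that (i) robust
within-window statistics remove the gross component, (ii) daily averaging
then window-level reduction suppress the noise component, and (iii) a
physiology-derived band catches whatever survives.

Because the mid-date (day 4 of 7) is the centre of the window, the mean
and the median of a linear ramp over the full window both equal the
mid-date value; the regression estimator recovers it exactly by
construction. This makes the clean-data limit a *fixed point* of the
whole pipeline — an exactness property the test suite asserts at 1e-9 kg
— and means estimator bias on real data comes only from noise, data
gaps, and curvature, not from the reduction itself.

## Stage choices and conventions

* **Quartiles** use linear interpolation of order statistics (the common
  scientific-software default), fixed so oracle tests are exact. The SD
  filter uses the sample (n−1) standard deviation. Both rules keep
  boundary values (removal requires strict exceedance), and both run
  within (animal, window) groups by default; groups with fewer than 4
  records pass through unfiltered because their quartiles/SDs are
  meaningless. Chaining the two rules is deliberately not offered — they
  are alternatives to be compared, not stacked.
* **Daily averaging** buckets by the timestamp's calendar date (no
  timezone arithmetic) and exists to stop high-visit days from dominating
  the window statistics.
* **Regression estimator**: OLS on the 1-based day index, mid-date held
  out, at least 4 non-mid-date daily points required; fewer points, or a
  degenerate predictor, yield a missing estimate rather than a guess. The
  fit is a closed-form centred solve, exact to ~1e-13 on noiseless input.
  The mean/median estimators do include the mid-date's own daily value
  when present; only the regression holds it out (it predicts that day).
* **Post-processing threshold**: `max(ADG_BW) × 30` kg, the maximum taken
  over the whole user-supplied target-ADG table. The factor 30
  deliberately covers a month of growth even though windows are 7 days:
  the band must tolerate anchor staleness and between-animal variation
  without trimming genuine growth ("prevent overfiltering"). Per-weight-
  class thresholds are available via `ADGTable.adg_for_weight` but are
  not the default.
* **Baseline policy** (the anchor of the plausibility band). Three
  readings are implemented: the animal's previous static-scale reference,
  its previous window estimate, and the current window's daily-weight
  median. The default is `window_median`, for two reasons decided at
  design time. First, deployment logic: a farm running an AWS precisely
  to avoid routine static weighing may have no recent reference, so the
  self-anchored band is the only universally available one. Second,
  error logic: a month-old anchor plus a band calibrated to exactly one
  month of maximum target gain leaves almost no headroom for a
  fast-growing animal — the band can then trim *clean* late-window days,
  which violates the principle that a correction stage must never widen
  error on clean data. The self-anchored band sits an order of magnitude
  above clean within-window variation (±36 kg vs. ±3 kg of trend plus
  ~2.5 kg of daily-mean noise), so it fires only on gross survivors.
* **Evaluation**: margins are inclusive and denominated by the reference
  weight; pairs with a missing estimate are excluded and counted. The
  non-parametric arm (Kruskal–Wallis + Dunn, Holm-adjusted by default)
  runs on per-animal paired differences so the large between-animal
  weight variance — which would otherwise swamp method differences — is
  removed by pairing rather than modelled; a mixed model is out of scope.
  Dunnett, Tukey HSD and Kruskal–Wallis come from scipy; Dunn's z-tests
  (with tie correction) are implemented in `awsproc.evaluate` since no
  post-hoc package is a dependency. Group batteries are reported both
  per window and pooled, labelled as such.

## The synthetic herd

`SimConfig` defaults encode the emulated study design: 36 steers, three
7-day windows in consecutive months (mid-dates 28 days apart), initial
weight N(330, 20) kg, per-animal ADG from N(0.8, 0.15) kg/day truncated
at ±2 sd, 4 visits/day, N(0, 5) kg visit noise, and 5% contamination
(+U(20, 80) kg or −U(60, 200) kg with equal probability). References are
exact by default — a calibrated static scale's error is negligible
against the effects under study.

Two generator choices deserve explanation:

* **Deterministic visit count.** Housed steers on a concentrate feeder
  attend every day, so the simulator emits exactly
  `round(visits_per_day_mean)` records per animal-day at random times.
  Randomising the count (e.g. Poisson) would add no information
  downstream — the pipeline consumes daily averages, so only day coverage
  matters — but it would silently break the clean-data fixed point: on a
  noiseless 7-day linear ramp the extreme value sits at 1.48 sample SDs
  from the mean, a hair inside the 1.5·SD bound, and any day-to-day
  count imbalance tips an edge day over the bound. A property that holds
  or fails on visit-count luck would test nothing.
* **Truncated ADG distribution.** Unbounded Gaussian tails occasionally
  produce steers gaining > 1.3 kg/day — beyond realistic growth for this
  class of animal, and enough to outgrow the ±36 kg band relative to a
  month-old anchor. Truncation at ±2 sd keeps every clean trajectory
  inside all bands by construction.

What the simulator does **not** model: diurnal gut-fill cycles, weight
loss/illness episodes, growth curvature, multi-animal platform occupancy,
and correlated contamination (e.g. feed build-up over days). Passing
tests therefore demonstrate that the algorithm behaves correctly under
its own assumptions (linear growth + iid noise + sparse gross errors),
not that real AWS data meet those assumptions. In particular the ~1 kg
synthetic RMSE is far below what field data produce, where biological
within-day variation dominates.

## Problem sizes and numerical details

The simulated study is 36 animals × 3 windows × 7 days × 4 visits =
3,024 records per run; the robustness-ordering checks aggregate 20
independent herds, and the test-battery calibration uses 2,000 null
datasets of 4 × 30 normal observations — sizes chosen to make stochastic
assertions stable at desk scale. Determinism: one master seed spawns
per-stage generators, so identical (config, seed) gives byte-identical
CSVs. Ties and degenerate inputs are decided explicitly: zero IQR or
zero SD keeps everything; a single record is its own daily average;
all-identical pooled samples define Kruskal–Wallis H = 0 (p = 1); and
constant identical groups give Dunnett p = 1 rather than 0/0.

## Known limitations

* The ADG table is user configuration; the packaged `EXAMPLE_ADG_TABLE`
  is synthetic (plausible magnitudes, not a published standard).
* The regression estimator is strictly linear; windows longer than ~2
  weeks would need curvature.
* The battery treats window estimates as independent across windows when
  pooling; repeated-measures structure is only addressed through the
  paired-difference arm.
* `animal_global` grouping and the `previous_reference` /
  `previous_estimate` baselines are provided for sensitivity analysis
  and carry the caveats described above.
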
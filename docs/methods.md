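# Methods

This note documents the models, parameter choices, and numerical
conventions behind `perchscale`, and what the synthetic-data tests do
and do not demonstrate about real recordings.

## Measurement model

A perch-scale is a 500 g load cell whose amplified, digitised output is
linear in applied mass. Two per-channel constants convert raw units to
grams:

    weight_g = (raw − zero_offset) / calibration_factor

`zero_offset` is the mean raw reading of the unloaded perch;
`calibration_factor` (raw units per gram) is the mean raw reading of a
known mass, minus the offset, divided by that mass. Both use the
arithmetic mean of a configurable number of readings (default 64),
matching hardware that already averages samples at acquisition. The
conversion and its inverse agree to better than 1e−9 g over the full
0–500 g range, and recalibration from identical readings is exactly
idempotent. Records carry a calibration timestamp so an analysis can
segment a stream at recalibration events. A channel whose factor is
mis-estimated by a factor *c* scales every converted weight by 1/*c* —
the signature the bias screen looks for. No drift model is included;
drift is handled operationally by recalibration.

## Synthetic signal generator

The generator emits the 1 Hz gram stream the logger would record, plus
per-second ground truth (true mass and occupancy state), so every
downstream stage can be scored exactly.

**True-mass trajectory.** Body mass follows a periodic daily profile:
linear decline through the dark period at `overnight_loss_rate`
(fraction of body weight per hour; by default derived from a 5 %
peak-to-trough diurnal amplitude over the 12 h night, i.e. ≈0.42 %/h,
and drawn per bird from the observed 0.2–0.5 %/h range in multi-bird
studies), then a fast post-fasting regain over the first 2 h of light,
a midday plateau at the daily mean, and a 2 h late-afternoon rise back
to the evening maximum. The day shape follows the standard avian
pattern — heaviest in late afternoon, lightest after the overnight
fast; a plateau-free all-day ramp would make the within-day weight
distribution nearly uniform and the daily mode ill-posed, contrary to
the sharply peaked histograms real perch-scales produce. With
`day_regain=False` the overnight losses accumulate instead. On top of
the daily profile, the daily mean performs a slow random walk
(`day_to_day_sd`, default 1 % of body weight per day) so that
longitudinal analyses have genuine day-to-day variation to track.

**Occupancy.** Overnight roosts are single lights-off→lights-on bouts
occurring with probability `roost_prob` = 0.4 per night — the rate
implied by 24 overnight sessions in 60 bird-nights of a six-bird,
ten-day study. Daytime use is an alternating renewal process:
log-normal bouts (mean 300 s, SD 300 s) separated by exponential
off-times tuned to a long-run perched fraction of `day_occupancy` =
0.3. The value reflects that a caged bird divides its day among
feeders, walls, and floor even when the perch-scale is its only true
perch, and it keeps the raw histogram baseline-dominated, as observed:
off-perch readings (uniform on [0, 1) g) form the largest class, the
15–25 g on-perch band the second.

**Artifacts.** Wing flaps (0–5 g, ~2 s, 6/h), partial-perching
plateaus (5–15 g with sensor-level jitter, ~30 s, 1/h), and impact
spikes (> 30 g, 1–2 s, 5/day) are marked Poisson events; rates are
assumptions chosen so artifacts stay a small minority (< 2 %) of
samples, since no quantitative rates are documented. Impacts — the
bird flying onto the perch — are drawn from daytime seconds only.
On-perch readings add Gaussian jitter (`sensor_jitter_sd`, default
0.06 g, mid-range of the device's 0.04–0.08 g repeatability measured on
inert objects); Gaussian noise matches the narrow, symmetric
fluctuations those control measurements show. A multiplicative
`calibration_bias` (default 1.0) scales every emitted value. Streams
are byte-identical across runs for a fixed config and seed.

**What the generator does not emulate:** second-scale postural noise
while perched (real birds shift and peck, which is why real data yield
far fewer qualifying stable windows than the simulation), feather or
dropping debris on the perch, temperature-dependent drift within a
day, and interactions between birds. Passing tests therefore
demonstrate correctness of the pipeline's logic and its behaviour
under the documented noise taxonomy, not performance on any particular
animal dataset.

## Filtering and daily estimation

Baseline filtering removes weights ≤ 1.0 g; the boundary is inclusive
so a reading of exactly 1 g — ambiguous between baseline and flap —
never enters an estimate. Band filtering keeps weights within ±30 % of
the bird's manual weight for that day (falling back to the nearest
preceding manual weight; if a bird has none, the band step is skipped
with a warning, as in pilot deployments without manual reference). The
30 % combines the 20 % humane-endpoint threshold with a 10 % allowance
for device bias, so a genuine welfare red flag can never be filtered
out; boundaries are inclusive so the kept set is closed. Both filters
conserve counts (kept + removed = input) and are idempotent.

The **daily mode** is the centre of the most populated histogram bin.
Bins are 0.01 g wide and centred on multiples of 0.01 g, so values at
2-decimal precision fall on bin centres; ties break to the lower bin.
The mode is computed after both filters (a switch allows
baseline-only filtering).

**Stable windows** slide with stride 1 over the filtered stream: every
run of 10 consecutive samples with sample SD (ddof = 1) at most 9 % of
the reference weight contributes its mean as one stable estimate.
Stride 1 maximises the number of estimates per day, consistent with
the thousands of stable estimates per day such systems report. Windows
are evaluated within contiguous segments only — a gap of more than 2 s
(missing rows, or samples removed by filtering) breaks the window — so
a "10-sample ≈ 10-second" window never spans an off-log interval. The
**daily stable estimate** is the mean of the day's stable estimates; a
day with none is excluded rather than imputed. For display, a centred
100-sample moving average smooths the stable-estimate series, with
edges using however many points are available.

## Overnight analysis

Sessions are maximal runs of above-baseline samples (internal gaps
≤ 5 s) overlapping the dark interval, searched within the interval
extended 1 h on each side so the first evening perch is captured; runs
shorter than 4 h are discarded and at most one session (the longest)
is kept per bird-night. The gap and duration defaults are exposed in
configuration since no canonical values exist. Each session gets an
ordinary least-squares fit of weight on elapsed hours
(`scipy.stats.linregress`); the total loss is the fitted line's drop
over the session, and the hourly loss fraction is reported against
both the manual reference weight and the session's own mean weight,
since either normalisation is defensible and they differ by a few
percent. Sessions with non-negative slope are excluded as "no weight
loss"; low r² is reported but never used for exclusion, because
unstable fits typically indicate device trouble rather than a
physiological difference, and no r² threshold is established. The
global summary is the unweighted mean and SD of |slope| across
retained sessions, with a per-bird breakdown.

## Validation and tuning

Daily estimates pair with manual weights by calendar date (manual
weighing happens once per afternoon; no intra-day alignment is
attempted). Agreement is summarised by MAE in grams and Pearson r with
a two-sided p. Fractional normalisation divides out each bird's mean
across days, making day-to-day changes comparable across birds; it
requires at least two days per bird and is scale-invariant.

The **bias screen** flags a bird when |mean signed error| exceeds 3×
the cross-bird median absolute signed error *and* exceeds an absolute
floor of 0.5 g. The floor is the scale of the device's typical daily
MAE: without it, the purely relative rule fires on milligram-level
differences between perfectly serviceable channels whenever all birds
happen to be accurate. With two birds carrying identical bias the
screen cannot flag either — it needs a majority baseline.

The **grid search** evaluates every (window length, SD fraction) pair —
default grid {5, 10, 20, 30} × {0.03, 0.06, 0.09, 0.12}, centred on
the operating point (10, 0.09) — by the pooled MAE of the daily stable
estimate against manual weights. The objective is a design choice (the
mode MAE is selectable); the score table is always exhaustive, and
ties break toward the smaller window, then the smaller SD fraction.

## Problem sizes and numerical conventions

The bundled studies use six birds for ten days (5.2 M samples) for the
monitoring scenario, 100 sessions of 6–10 h for slope-recovery checks,
and six 24 h inert-object runs — sizes at which every statistic of
interest is estimated to well below its tolerance while the full suite
runs in about a minute. Seeds are threaded through
`numpy.random.default_rng` everywhere; child seeds stay below 2³¹.
Timestamps are naive local time at 1 s resolution; weights are written
to CSV at 2 decimals (one digit beyond the device's 0.1 g precision,
making file round trips lossless). Degenerate inputs (empty days,
single-sample windows, never-calibrated channels, zero-variance
correlations) raise explicit errors or return explicit absences — never
silent NaNs.

## Known limitations

* The stable-window SD criterion needs a reference weight; without any
  manual record the day's median filtered weight stands in, which can
  admit windows around a systematically wrong level.
* The bias screen detects relative, persistent offsets only; a fleet
  in which most channels share the same bias passes unflagged.
* Session detection assumes the dark interval is known from the light
  schedule; free-running light cycles are out of scope.
* The daily mode is sensitive to secondary density bands (e.g. a long
  evening roost at a weight above the daily mean) and can land a few
  tenths of a gram from the daytime mean on such days; the stable
  estimate is the more robust daily summary, and the two disagreeing
  is itself a useful diagnostic.
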
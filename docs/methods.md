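# Methods

This note documents the modelling choices, defaults, and limitations of
`routinewatch` — what the pipeline assumes, why the knobs have the values
they have, and what the synthetic experiments do and do not demonstrate.

## From event logs to dedication tables

The ingest pipeline assumes the activity-recognition stage upstream is a
solved problem: every sensor event arrives with an activity label, and we
treat the label stream as ground truth. Consecutive events sharing a label
form an episode. Because sensor events are instantaneous readings, an
episode is taken to **end where the next episode begins** (half-open
coverage): the recognised activity persists until a different one is
recognised. This yields full-day coverage and sleep fractions around a
third of the day, which matches what dedicated sleep episodes should look
like; the alternative convention (episode ends at its own last event) is
available via `end_convention="last_event"` but systematically
under-counts quiet activities. The final episode of a log necessarily ends
at its own last event.

Days are framed at civil midnight in the log's naive local timestamps; no
timezone or DST handling is attempted. Dedication uses a fixed 86,400 s
denominator even for partially observed days, and each user's first and
last calendar day are dropped by default (`drop_boundary_days=True`)
because they are almost always truncated by installation and removal.
The activity vocabulary is the union of labels observed across all users,
sorted lexicographically and frozen; `Other_Activity` is removed after
accounting (it is a catch-all with no predictable structure). Values are
kept at full precision internally and rounded only when writing CSV
(2 decimals by default).

## Windowing and evaluation protocol

Splitting is chronological *within* each user — first ⌊0.7·m⌋ days to
train, rest to test — so both subsets contain every user and no test label
precedes a training day. Windows are built within each subset
independently and never span a gap of missing calendar days (the window
restarts; `allow_gaps=True` disables this). A user block of m consecutive
days yields m − w + 1 samples.

Per-day errors average over activities first (MAE = mean |a − â|,
MSE = mean (a − â)²), and dataset scores average over days; everything is
on the percentage scale. Cross-validation uses k = 3 contiguous-in-time
blocks per user, preserving chronology inside folds; a `shuffled` mode
exists for comparison but interleaves past and future and is therefore
leakage-prone. Fold dispersion is reported as the population standard
deviation. Model comparison uses a two-sided paired t-test on per-fold
MSE, with the degenerate conventions: identical score vectors give p = 1,
constant nonzero differences give p = 0.

## Recurrent architectures and training numerics

All four recurrent families are built from LSTM cells over the w − 1 input
days and end in a rectified dense layer mapping to the t activities (so
predictions are non-negative, matching the dedication domain):

- **rnn** — 1–2 stacked LSTM layers;
- **bi_rnn** — bidirectional layers (forward and reverse passes
  concatenated per step);
- **conv_lstm** — a 1-D convolution over the time axis, then LSTM;
- **attention_rnn** — LSTM returning the full sequence, an additive
  attention layer (score = v·tanh(W·h + b), softmax over time steps) that
  re-weights each step by its attention weight, then a second LSTM.

The attention weights are non-negative and sum to one over the window;
they are exposed (`last_attention_weights`) for inspection. The networks
run on a small reverse-mode autodiff engine over numpy arrays written for
this package; gradients of every architecture are tested against central
finite differences.

Training follows the shared recipe: Adam (β₁ = 0.9, β₂ = 0.999), MSE
loss, batch size 128, 80 epochs, learning rate 0.1 by default. Two
numerical choices matter in practice:

- **Input scaling** (`ModelSpec.input_scale = 100`): dedication
  percentages are divided by 100 before the first layer. Raw values up to
  ~60 saturate the tanh/sigmoid gates and make training erratic; outputs
  remain on the percent scale.
- **Output-bias initialisation**: `train_predictor` starts the final
  rectified layer's bias at the per-activity training-label means. A
  zero-initialised bias can leave output units dead under the rectifier
  (zero output, zero gradient), which shows up as a model stuck predicting
  all zeros.

The default learning rate of 0.1 is aggressive; it is kept as the
headline default but the synthetic reference experiments
(`routinewatch.experiments`) train at 0.01 for 20 epochs, where
convergence is reliable across seeds at the default corpus scale.
Training raises on non-finite loss rather than silently continuing.
Hyperparameter search samples uniformly at random from the declared
ranges (layer counts 1–4, conv filters/kernel 2–64, units 8–256, dropout
0–0.4) for 25 seeded trials and returns the test-MSE argmin with the full
trial log.

The default window is w = 15: the input then covers two full weeks —
two weekends and at least two of every weekday — which is the smallest
window with that property and the best-performing one in our experiments.

## Two-step anomaly detection

Step 1 fits a normal distribution to the per-day MAE vector using the
population form (denominator n) for both μ and σ, and flags days with
z = (ε − μ)/σ **strictly greater** than Z = Φ⁻¹(p). The test is
one-sided: unusually *small* errors are unremarkable. The default
p = 0.925 balances sensitivity against false alarms; lower values
(0.85–0.9) suit fragile populations where small deviations matter, higher
values (0.99) suit healthy populations where only strong deviations are
of interest. With the threshold fitted and applied to the same Gaussian
sample, the flag fraction converges to 1 − p; this calibration is
asserted at n = 100,000 in the acceptance suite.

Step 2 computes per-activity boxplot whiskers (Q1 − 1.5·IQR,
Q3 + 1.5·IQR; quartiles by linear interpolation between closest order
statistics — the convention matters and is frozen) over a reference
population, pooled across users. A flagged day is reported only if at
least one activity falls strictly outside its whiskers; ties are
non-anomalous. By default the reference population and the error model
are estimated on the **training subset only** and applied to both subsets,
avoiding test-set leakage; `reference=pooled` estimates them over all
days instead. Whiskers include zero-dedication days. The reference
recovery experiment uses the pooled error model: σ fitted on training
errors alone under-states the spread of held-out errors by the
generalisation gap, which inflates the test-day flag rate above its
nominal 1 − p level; pooling keeps the z-scores calibrated on the days
being scored.

Reports carry the calendar day, a per-user ordinal, the z-score, and the
deviated activities with direction and violated limit. Step 2 can only
shrink the step-1 set — the gating is asserted as an invariant.

## The synthetic population

The generator emulates the structure the detector relies on:

- **Archetypes** (three by default: homebody, active, social) scale a
  shared base profile whose largest components are Sleep (~31% of the
  day) and TV watching (~7.5%), with 41 activities totalling ~79%;
  the remainder is implicit `Other_Activity` time.
- **Weekly periodicity**: weekend multipliers raise sleeping, TV and
  guest entertainment and suppress work-type activities.
- **Population heterogeneity**: a per-user Gaussian random effect
  (sd 0.25) on the log-odds scale.
- **Daily noise**: independent logit-normal per activity
  (value = 100·sigmoid(logit(mean/100) + ε), ε ~ N(0, s), s = 0.35 for
  most activities). Logit-normal was chosen over a Dirichlet because
  per-activity dispersions are independently controllable, mirroring the
  strongly heterogeneous per-activity standard deviations of real
  corpora. Days whose total would exceed the 97% coverage cap are
  rescaled (rare at defaults).
- **Scale**: 30 users × 75 days × 41 activities, matching the size of the
  real single-resident corpora this kind of system is built on.

The manifest records every user's archetype and latent per-day means, so
expected quantities have closed forms. In particular the mean baseline's
test MSE is computable as the between-day variance of the latent means
plus the delta-method noise variance (100·p(1−p)·s)², ignoring the rare
rescaling events; the reference experiment asserts a trained recurrent
model beats this closed-form bound.

Injected anomalies shift one activity past the reference upper whisker
(default: Watch_TV to whisker + 10 points) and conserve the day total by
taking the time from a donor activity (default Sleep) — large enough by
construction to trip both detector steps. The event-stream renderer
realises each active activity as one contiguous episode per day with
residual time as `Other_Activity`; re-ingesting recovers the table to
well under 0.01 percentage points per cell (the only loss is a 1 ms
sentinel before each final episode event).

**What the synthetic experiments do not show**: real routines have
correlated activities, drifting habits, recognition errors, missing
sensor spells, and anomalies far subtler than a 10-point whisker
exceedance. Passing the recovery study demonstrates the pipeline's
plumbing and calibration, not clinical sensitivity.

## Degenerate inputs and edge conventions

- Users with fewer than two days are excluded from splitting, with a
  warning.
- An all-equal error vector cannot be z-scored; fitting raises.
- A constant activity column collapses its whiskers to a point; any other
  value is a deviation.
- k-means with k equal to the number of days is allowed but warned about
  (silhouette is reported as the degenerate 1.0).
- Negative interval durations and infeasible archetypes (modulated means
  summing over 100%) are fatal, not clipped.

## Problem sizes used in the reference experiments

Calibration uses 100,000 simulated errors; the recovery study uses the
default 30 × 75 × 41 corpus (1,140 training windows, 270 test days at
w = 15), 5 injected anomalies, and the 20-epoch/0.01 learning-rate
recipe; clustering uses the same corpus. These sizes were chosen so the
entire reference suite re-runs from scratch in well under a minute on a
single CPU while leaving comfortable statistical margins.
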
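# Methods

## Problem and scope

`nocturne` predicts a binary nocturnal-hypoglycemia (NH) label for the
night 22:00–07:00 from data recorded during the preceding day 10:00–22:00
in children with type 1 diabetes: fused CGM/SMBG glucose, wearable
physiology, and static anthropometrics.  The prediction horizon is the
whole 9-h night, i.e. a bedtime risk assessment rather than a short-horizon
alarm.  A second, shorter-horizon scheme (15 min ahead, sliding windows
inside the night) is included as a benchmark for dataset quality.

## Curation model

Glucose arrives from two sources: a sensor stream (5- or 15-min native
step) and fingerstick SMBG entries.  Both report at minute precision, so
"the same timestamp" is operationalized as the same 5-min grid slot after
flooring; exact-equality matching would almost never fire.  When both
sources occupy a slot, the lower value is kept — a deliberate pessimistic
bias, since missing a hypoglycemic excursion is the costly error in this
application.  The fused record list is interpolated to the uniform 5-min
grid by time-weighted linear interpolation; grid points outside the record
span remain missing and are filled with the mean of that calendar day's
non-missing values, each sample carrying provenance
(`measured`/`smbg`/`interpolated`/`gap_filled`).  A calendar day with no
observed values at all is an error rather than silently imputed.

Wearable channels are cleaned per channel: duplicated timestamps are
replaced by their mean (sensors are swapped daily, producing overlaps); a
sample with a device quality score strictly below 50 % is dropped (quality
exactly 50 stays); a participant-day-channel is kept only if at least 30 %
of the expected native-rate samples survive; surviving samples are averaged
in non-overlapping half-open 5-min windows `[t, t+5)` labeled by window
start, and empty windows are day-mean-filled like glucose.  The
availability rule is applied per channel (whether the original protocol
applied it per channel or per sensor-day is not documented; per-channel is
the stricter, more auditable choice and every decision is logged with its
fraction).

Activity classes are a categorical stream; windows take the modal class and
map it to MET intensity (1 MET = 1 kcal/kg/h) via a fixed 27-class table.
Classes without a defined intensity (`Undefined`, `Other`, device
maintenance classes) map to missing, not zero.

Day retention for pairing: a calendar day enters the labeled dataset only
when measured/SMBG-provenance samples cover ≥ 30 % of the 10:00–22:00 grid.
Pure interpolation can bridge arbitrarily long gaps, so without this rule a
fully absent day would re-enter the dataset as wall-to-wall interpolated
values.

## Label definition

A night (22:00–07:00) is NH when either (1) any SMBG reading is strictly
below 3.9 mmol/l, or (2) a maximal run of consecutive 5-min grid samples
all strictly below 3.9 mmol/l covers more than 15 min.  Each sample covers
its half-open slot, so a run of k samples covers 5k minutes and clause (2)
requires k ≥ 4 on the 5-min grid; the alternative (k−1)·5 convention would
make a 4-sample run exactly 15 min and ambiguously excluded.  Gap-filled
samples participate like measured ones (labels are assigned on curated
data); `include_gap_filled=False` excludes them.  A night with no glucose
and no SMBG is excluded with a log entry rather than guessed.  Event
detection is verified against a brute-force oracle that enumerates every
sub-interval of randomized night traces.

## Features

The eight glucose-dynamics statistics are named but not formula-defined in
the clinical literature that motivates them; the package adopts the
standard definitions and keeps each behind one function so variants can be
swapped:

| feature | definition | units |
|---|---|---|
| CV | sample SD / mean | — |
| lability index | mean over consecutive pairs of (ΔG)²/Δt | (mmol/l)²/h |
| LBGI | mean of 10·f(G)² over samples with f(G)<0, f(G)=1.509((ln G_mg/dl)^1.084−5.381), 18.016 mg/dl per mmol/l | risk units |
| CONGA-1h | sample SD (n−1) of G_t − G_{t−60 min} | mmol/l |
| minimum | min over the window | mmol/l |
| last difference | G_T − G_{T−1} | mmol/l |
| acceleration | G_T − 2G_{T−1} + G_{T−2} (backward second difference of the final three samples) | mmol/l per step² |
| linear trend | OLS slope of G on time | mmol/l per h |

The generic feature bank computes 22 named shape statistics per channel
(moments, range/IQR, slope, energy, mean absolute change, runs and counts
about the mean, autocorrelations at lags 1/6/12, extremum positions, and an
emptiness flag).  It deliberately replaces exhaustive automated
featurization (~800 features per channel): a compact, deterministic,
fully-named catalogue keeps wrapper-based selection tractable and testable,
and is the documented extension point.  Degenerate inputs emit zeros plus
the flag, so feature matrices never contain missing cells.

Sequential forward selection greedily adds the feature maximizing mean
validation F2 of the downstream classifier over an internal stratified
3-fold split of the training data; ties break by column order, making the
result deterministic under a fixed seed.  Static features compete with
temporal ones rather than being exempt.

## Models and evaluation

Class weights are inversely proportional to class frequency,
w_c = N/(2·N_c) (e.g. 48 negative / 18 positive nights give 0.6875 /
1.8333).  Families:

- **L1 logistic regression** — penalty strength chosen by internal 3-fold
  cross-validated F2 over a logarithmic grid (10⁻²…10², 7 points), since
  no penalty value is prescribed by the protocol.
- **Random forest** — 10 trees, class-weighted.
- **Recurrent networks** — written in numpy on a small reverse-mode
  autodiff (verified against finite differences): scenario A is
  mask → bidirectional GRU(32) → dropout 0.2 → LSTM(16) → dropout 0.2 →
  dense sigmoid on the 144-step day grid; scenario B fuses an LSTM(16)
  temporal branch with a dense(16, ReLU) static branch through a dense(16,
  ReLU) head.  tanh recurrent activations, ReLU dense activations, Adam at
  learning rate 0.001, batch size 1, class-weighted binary cross-entropy,
  early stopping on validation F2 with patience 5 over at most 30 epochs.
  Layer widths are the package's own choice (the original hyperparameter
  search is out of scope); they are deliberately small for a dataset of
  tens of nights.  Masked timesteps (gap-filled or absent; exactly 0 after
  standardization) leave the hidden state unchanged.
- **MLP** — dense(16, ReLU) ×2 with the same training loop, used by the
  replication scheme.

Metrics: specificity, sensitivity, precision, F1, F2 and AUC (rank
statistic with tie correction, verified against brute-force pair counting).
Predicted positive means score ≥ 0.5; no threshold is prescribed by the
protocol, so the conventional 0.5 on probabilities is used.
Zero-denominator ratios report 0 with a `degenerate` flag instead of
raising.

Cross-evaluation: stratified 6-fold, repeated 5 times with re-shuffled
partitions; for the neural families a stratified 20 % validation carve-out
is taken from each training split.  Per-run metrics are computed from the
pooled test-fold predictions, and the report gives mean ± SD across the 5
runs (SD across individual folds is also emitted, since either convention
is defensible).  Partitions are derived from labels and the master seed
only, so every dataset combination within a run sees identical folds.

## 15-min replication scheme

Nights are scanned midnight–06:00 with 45-min windows advancing 20 min,
predicting the glucose state exactly 15 min after each window's end; 16
windows fit per night (00:00–00:45 → 01:00 through 05:00–05:45 → 06:00).
The window label is the sub-threshold state of the single grid sample at
the target time (an SMBG within half a grid step of the target also
counts).  Window features are the eight glucose statistics plus age, BMI
and sex; CONGA's lag is reduced to 15 min inside windows because a 1-h lag
cannot fit a 45-min span.  Windows whose target sample is missing are
skipped.

## Synthetic cohort generator

The generator emulates the study conditions, not glucose physiology: the
pipeline is under test, so a process with analytically checkable moments is
preferable to a mechanistic glucose–insulin model.  Defaults: 13
participants (ages uniform on [7.5, 13.9] years, 4 female, BMI drawn around
19.8 ± 4.4 kg/m² and weight derived from BMI and an age-linked height so
the BMI invariant holds by construction), 6 scheduled days each, 12
scheduled participant-days absent → 66 analyzable nights; 5 of 13
participants carry a 5-min-native sensor, the rest 15-min (exercising the
interpolation path).

Daytime glucose follows an Ornstein–Uhlenbeck process (reversion 1/h,
noise 1.1 mmol/l·h^(−1/2)) around a target of 8 mmol/l plus Gaussian meal
bumps (2.5 mmol/l at 08:00/12:30/18:30) minus an exercise effect of
0.10 mmol/l per accumulated MET·h.  Exercise bouts come from a three-slot
menu (60 min at MET 7, 60 min at MET 6, 45 min at MET 10), each kept with
probability 0.75 and duration jittered ±50 %, giving a realized daily load
of ≈ 15 ± 6 MET·h.  SMBG entries are taken hourly during bouts with
0.3 mmol/l fingerstick noise.  The wearable emits heart-rate (with quality
scores that dip during motion, some below the 50 % gate) and motion
channels at a 1-min native step — a deliberate resolution choice for the
generator; availability denominators use the configured native step — plus
one dropout segment per day (12 % of the day).

Night truth: NH ~ Bernoulli(σ(α + β_met·MET·h − β_g·G_bed)) with
β_met = 0.35 per MET·h, β_g = 0.40 per mmol/l, and α = −4.63 calibrated by
Monte Carlo so the expected NH rate at the default effect sizes is ≈ 18/66.
The exercise effect enters the night only through this logit — no
mechanistic carry-over — so the generative truth is exactly the hypothesis
the classifiers must detect.  An NH night receives a contiguous dip to
3.0 mmol/l lasting 40 min (> 15 min by construction) starting uniformly in
23:00–05:00, optionally with one symptom fingerstick inside it; nights
without an injected dip are floored at 4.2 mmol/l.  The floor is what makes
`truth.json` exact: the labeling module provably agrees with the recorded
truth (boundary-grazing dips are excluded by construction).  All
randomness flows from one master seed through named substreams (cohort,
day, night, noise, attendance) so stages can be regenerated independently.

What the generator does **not** emulate: insulin dosing and carbohydrate
intake, sensor error models (MARD), circadian glucose structure beyond
meals, sleep staging, and inter-night dependence.  Passing tests therefore
demonstrate that the pipeline recovers a known activity→night causal link
under realistic sampling, imbalance and missingness — not that any model
generalizes to real pediatric data.

## Problem sizes and numerical choices

- Camp-scale runs use the default 66-night fixture; effect-recovery and
  null checks use 510-night cohorts (30 participants × 17 days), the scale
  at which cross-validated AUC separates cleanly from the chance band.
- The null suite (effect slopes zero) brackets chance performance at AUC
  ∈ [0.4, 0.6] on 510 nights; the effect cohort must exceed that band
  (observed ≈ 0.70–0.72 across seeds).
- Interpolation uses exact time weighting on nanosecond timestamps;
  resampling windows are half-open to prevent double counting; SMBG at
  exactly 3.9 mmol/l is not an event (strict inequality).
- Selection and cross-evaluation derive all randomness from
  `RunConfig.seed`; derived seeds stay below 2³¹.

## Known limitations

- The recurrent families train in seconds-to-minutes per fold (numpy,
  batch 1); full 6×5 cross-evaluation of the DNN scenarios on the 144-step
  grid is supported but slow, and the default experiment grid therefore
  runs the two baseline families.
- Feature definitions for the eight glucose statistics are declared, not
  inferred from the motivating study (which names but does not define
  them); alternates can be swapped behind the per-feature functions.
- The time zone of wall-clock windows is configurable but defaults to
  Central European time; daylight-saving transitions inside a study period
  are handled by the tz-aware arithmetic but untested against real device
  exports.
- Only CSV ingest is supported; proprietary device export parsing is out
  of scope.
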
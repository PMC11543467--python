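# nocturne

Predicting nocturnal hypoglycemia in children with type 1 diabetes from
daytime data.

Children with type 1 diabetes (T1D) frequently experience nocturnal
hypoglycemia — glucose dropping below 3.9 mmol/l during the night — and
daytime physical activity is the dominant risk factor.  `nocturne` is a
reusable pipeline that asks the clinically relevant question at bedtime:
*given everything measured today (10:00–22:00), will tonight (22:00–07:00)
be hypoglycemic?*  It is aimed at researchers working with continuous
glucose monitoring (CGM), SMBG logbooks, and wearable physiology in
pediatric cohorts.

The pipeline covers:

- **Curation** — CGM/SMBG fusion (the lower value wins on a shared 5-min
  slot, the pessimistic choice when hypoglycemia is the target),
  time-weighted linear interpolation to a uniform 5-min grid (3.33 mHz),
  day-mean gap filling; wearable duplicate averaging, a 50 % quality gate,
  a 30 % per-day availability filter, 5-min window means; mapping of
  activity classes to metabolic equivalents (1 MET = 1 kcal/kg/h).
- **Labeling** — a night is hypoglycemic when (1) any SMBG < 3.9 mmol/l, or
  (2) an interval > 15 min has all CGM samples < 3.9 mmol/l.
- **Features** — eight glycemic-dynamics statistics (CV = s/μ; lability
  index = mean (ΔG)²/Δt; LBGI = mean 10·f(G)²·1[f<0] with
  f(G) = 1.509((ln G_mg/dl)^1.084 − 5.381); CONGA-1h = SD of 1-h lagged
  differences; minimum; last difference; acceleration; OLS trend), a
  generic per-channel time-series feature bank, and greedy sequential
  forward selection to the 15 features maximizing validation F2.
- **Models & evaluation** — L1 logistic regression, random forest
  (10 trees), and masked GRU/LSTM recurrent networks (numpy, Adam, batch 1,
  class-weighted loss, F2 early stopping), all with class weights
  w_c = N/(2·N_c); six metrics (specificity, sensitivity, precision, F1,
  F2, AUC) with F2 = 5·P·S/(4P + S) as the headline score; stratified
  6-fold cross-evaluation repeated 5 times with shared partitions across
  dataset combinations.
- **Replication scheme** — a 15-min-horizon benchmark: 45-min sliding
  windows every 20 min over midnight–06:00 (16 windows per night), window
  features + age/BMI/sex, LR / RF / MLP.
- **Synthetic cohort** — because the motivating camp dataset is private, a
  generator emulates it: 13 children over 6 days (66 analyzable nights),
  mean-reverting glucose with meals and exercise bouts, wearable channels
  with quality dropouts, and nights drawn from
  `NH ~ Bernoulli(σ(α + β_met·MET·h − β_g·G_bedtime))`, with exact
  ground-truth bookkeeping.

## Worked example

```bash
nocturne synth --seed 1 --out-dir camp/      # synthetic cohort CSVs + truth.json
nocturne label --data-dir camp/ --out-dir out/
# -> 66 nights, 15 hypoglycemic -> out/labels.csv
nocturne train-eval --data-dir camp/ \
    --combinations glucose_literature_features --families random_forest \
    --out-dir out/ --seed 1
```

The last command prints a Table-shaped matrix such as

```
| model         | metric | glucose_literature_features |
|---------------|--------|-----------------------------|
| random_forest | F2     | 35.9 ± 10.8                 |
| random_forest | F1     | 31.4 ± 8.0                  |
| random_forest | AUC    | 52.3 ± 5.1                  |
```

meaning: over 5 repetitions of stratified 6-fold cross-evaluation on the 66
labeled nights, a 10-tree random forest on the eight glucose-dynamics
features reached a mean F2 of 35.9 % (SD over the 5 runs 10.8 %).  At this
camp-sized sample the scores move considerably with the seed — exactly the
behavior repeated cross-evaluation is there to expose.  On larger synthetic
cohorts (≈500 nights) the same features recover the generator's
activity-to-night causal link with AUC ≈ 0.70–0.72 against a null cohort at
≈ 0.50 (see below).

Equivalent library calls: `synthetic_data.generate`,
`experiments.curate_cohort`, `experiments.build_feature_matrix`,
`model_eval.run_cv`.

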
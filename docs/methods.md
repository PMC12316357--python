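# Methods

## Problem setting

`tgehr` implements a risk-prediction pipeline for primary hip/knee
replacement from coded primary-care visit streams, predicting the outcome 1
or 5 years in advance. The pipeline covers synthetic EHR generation, cohort
assembly with exact case-control matching, a temporal-graph representation
of each patient's visit history, a convolutional risk model with learnable
exponential time-decay edge weighting (TG-CNN), atemporal comparison models,
prevalence recalibration, and a calibration/discrimination evaluation suite.

The source data this design targets (UK primary-care records coded in CTV3,
1999-2014) are not distributable, so every stage runs on, and is validated
against, the package's own synthetic generator. The generator's role is not
to imitate any particular dataset but to provide *controlled truth*: data
whose signal content is known exactly, so that chance-level and
recoverable-signal behaviour of the full pipeline can be asserted.

## Temporal-graph representation

Each patient's censored history is a sequence of visits (distinct calendar
dates). Nodes are the V most frequent clinical codes (ties broken
lexicographically) plus six fixed prescription-group tokens — opioids,
non-opioid analgesics and NSAIDs, each split acute/repeat — giving
N = V + 6 nodes. For every pair of consecutive retained visits, a directed
edge runs from each code at the earlier visit to each code at the later
visit (cross-product), carrying the elapsed time in months
(Δdays / 30.44, the mean Gregorian month). Only the last `k_max` visits are
retained. The result is a sparse tensor of shape (k_max − 1, N, N).

Choices worth noting:

* **Front padding.** Short histories occupy the *trailing* slices, so the
  most recent transition always sits at slice k_max − 2. This pins the
  recency signal to a fixed tensor position for the convolution.
* **No within-visit edges.** Same-date codes share a time step; a zero
  elapsed time would be indistinguishable from absence in a sparse store.
* **Out-of-vocabulary codes** are dropped silently but counted per patient.
  At study scale the top-512 vocabulary covers >99% of events, so the loss
  is marginal by construction; the synthetic corpus reproduces this
  concentration (Zipf exponent 1.4 over a 2000-token pool puts ≥95% of
  events in the top 512).
* A patient with fewer than two in-vocabulary visit dates cannot form a
  graph and is excluded, mirroring the two-visit eligibility rule; when one
  member of a matched pair is excluded this way, the partner is dropped too,
  keeping the training set exactly balanced.

## The TG-CNN

Pipeline, for a tensor T and demographics d:

1. **Decay weighting.** Every nonzero edge Δt becomes exp(−γ·Δt) with γ > 0
   learnable (stored as log γ, so positivity is structural). Recent
   transitions therefore weigh more; γ sets the timescale.
2. **Count normalization.** Each slice is divided by its number of nonzero
   edges (the usual degree normalization of graph convolutions). Consecutive
   visits with many codes produce cross-product edge counts that vary by
   orders of magnitude; without normalization these counts dominate every
   aggregate and drown the decay-weight values.
3. **3D convolution.** Each of `n_filters` filters spans `filter_depth`
   consecutive slices over the full N × N adjacency and emits one ReLU
   activation per slice window, producing a temporal feature sequence.
   Each filter is parameterized as a zero-mean weight tensor plus a
   *learnable scalar mean component* (filter = W + s·1). The two pieces are
   mathematically one filter, but the split matters for optimisation: the
   gradient of aggregate edge-mass statistics concentrates in s instead of
   diluting across the D·N·N positions, so value-based (gap-time) signals
   are learned as quickly as positional (code-identity) ones.
4. **Recurrent aggregation.** A tanh recurrence reduces the activation
   sequence to a fixed hidden vector; the front padding guarantees the
   final step corresponds to the most recent window.
5. **Demographic fusion.** Age (z-scored on the training folds), a female
   indicator and four IMD-quintile indicators (quintile 1 reference) are
   concatenated to the hidden vector.
6. **Head.** A dense layer with sigmoid yields the raw probability on the
   balanced-data scale.

Training minimises binary cross-entropy with Adam; l2 is available but off
by default (the adopted variant is the one without l2). Early stopping
monitors the held-fold loss. One model is fitted per cross-validation fold;
test-time prediction averages the fold models. All gradients are
hand-derived NumPy and verified against central finite differences to
relative error < 1e-4 in the test suite.

Two regularizers control desk-scale overfitting (training sets of a few
hundred patients cannot support ~30k free positional weights):

* **edge dropout** (default 0.25): nonzero edges are dropped at random
  during training (inverted scaling), destroying per-patient positional
  fingerprints while aggregate decay statistics survive in expectation;
* **width-aware learning-rate damping** (default 0.1) on the conv weight
  matrix only, so the low-dimensional pathways (scalar mean components, γ,
  recurrence, head) train at full speed while the positional matrix moves
  an order of magnitude more slowly.

Without these, the conv memorizes small training sets exactly (training
AUROC 1.0, test AUROC ≈ 0.5 on gap-only signals); with them the same
architecture recovers gap-time signals to test AUROC ≈ 0.95.

Key invariances, all property-tested: outputs lie strictly in (0, 1);
scaling every Δt by c and γ by 1/c leaves predictions unchanged; in the
large-γ limit predictions become independent of the gap values; an all-zero
tensor yields a constant (demographics-only) prediction.

## Cohort assembly

* **Outcome.** Cases carry a primary-replacement token; the index date is
  its *first* occurrence. Controls receive a seeded reference date drawn
  from the empirical distribution of case index dates, so control histories
  are censored comparably (avoiding immortal-time artefacts).
* **Censoring.** All feature builders see only events strictly before
  index/reference date minus the horizon (1 or 5 years). The censoring
  function asserts this invariant programmatically on every run.
* **Eligibility.** Age 40-75 at the window start; at least two distinct
  visit dates in the horizon-length window before the index date; no
  revision/modification code before a primary code; controls with revision
  codes removed. One reason is logged per excluded patient, rules applied
  in a fixed order.
* **Leakage stripping.** Replacement-related hospital referral codes are
  removed from the event stream before anything downstream sees it.
* **Splits.** A seeded uniform 10% test split (unmatched — it keeps the
  natural imbalance) and a 10% calibration slice (also imbalanced, used
  only to fit the recalibrator; one defensible reading of "data not used in
  training"). In the remainder, each case is matched to exactly one unused
  control with identical integer age, sex and IMD quintile, via a
  seeded-shuffle greedy pass. With an exact 3-way key, greedy attains the
  maximum matching within every key group (proved by the 100-cohort
  brute-force comparison in the tests), so no assignment solver is needed.
  Unmatched cases are dropped and logged. Matched pairs are co-assigned to
  folds (sizes differing by ≤1 pair) to prevent within-pair leakage across
  folds.

## Baselines

Logistic regression and random forest (scikit-learn, library defaults,
seeded) consume code counts over the same vocabulary plus the same
demographic encoding — no temporal information of any kind. The RNN
baseline consumes the order-preserved code-index sequence of the last k_max
visits (no gap times, no demographics) through a single-layer tanh
recurrence over learned embeddings, implemented in NumPy with
finite-difference-checked gradients. All models train on byte-identical
matched splits and are recalibrated by the identical procedure, so metric
differences are attributable to the models.

## Evaluation and recalibration

* **AUROC**: pairwise concordance (ties ½), delegated to scikit-learn and
  verified against all-pairs enumeration on 500 random instances.
* **AUPRC**: step-wise non-interpolated estimator (average precision),
  verified against an explicit threshold sweep. For a label-independent
  scorer AUPRC approaches the positive prevalence, which is therefore the
  informativeness floor reported alongside it.
* **C-slope**: slope of a logistic GLM of outcomes on logit(probability).
  The regression is on the logit scale — the scale on which perfect
  calibration gives slope exactly 1; slopes below 1 indicate
  over-dispersed (overfitted) probabilities, above 1 over-shrunk ones.
* **Wald 95% CIs**: point ± 1.96·se, with Hanley-McNeil se for AUROC, a
  logit-scale binomial approximation with effective n = number of positives
  for AUPRC, and the GLM se for the C-slope. Wald intervals under-cover
  slightly in small samples; the suite checks ≥90% empirical coverage at
  n = 2000.
* **Recalibration**: logistic GLM with logit(raw) as the single covariate,
  fitted on the held-out imbalanced calibration slice. Rank metrics are
  bit-identical before/after whenever the fitted slope is positive
  (asserted on every pipeline run). Probabilities are clipped at 1e-6
  before logit transforms.
* **Threshold metrics**: PPV/sensitivity/specificity at a configurable
  threshold (default 0.5 on recalibrated probabilities); PPV is reported as
  0 when no positive prediction is made.
* **Calibration curves**: 10 equal-frequency bins of predicted probability;
  single-class bins report a rate of 0 or 1 rather than erroring.
* **Subgroups**: the full panel repeats per sex and per IMD quintile;
  groups under 30 patients (or with one outcome class) are flagged, not
  computed.
* **Model comparison**: a seeded patient-level bootstrap on the shared test
  set replaces unspecified two-sample testing; it reports the observed
  metric difference, a percentile interval and a two-sided p-value.

## Synthetic generator

What it emulates: a 15-year observation window; ages 40-75 uniform at the
window start; 62% female; IMD quintiles uniform; mean visit counts graded
by IMD from 54.6 (most deprived) to 82.9 (least deprived); up to 10
distinct clinical codes per visit (1 + Poisson(1.5), truncated);
Zipf-distributed codes (exponent 1.4, pool 2000); six prescription tokens;
a target outcome prevalence (default 0.30); and for cases an inhomogeneous
Poisson ramp over the final 2×horizon years before the replacement date in
which both visit rate and the mixture weight of precursor pain codes and
prescriptions rise linearly, scaled by `signal_strength`. A small fraction
of patients carries revision-before-primary, revision-only and
pre-replacement referral code patterns so the exclusion and
leakage-stripping rules are exercised. Mortality is not simulated (the
population this mirrors had a negligible mortality rate), dates are
otherwise uniform, and sex is binary as in the source coding.

The `temporal_signal_only` mode is the controlled experiment behind the
temporal-advantage claim: both classes draw the same visit count, the same
total record span, and the same i.i.d. code mixture; only the *shape* of
the gap sequence differs (case gaps shrink geometrically toward the censor
date, with a 1.5-day floor so calendar-day rounding never merges visits and
leaks the class into visit counts). Count-based representations are
uninformative by construction; all discrimination must come from edge
times.

What it does not emulate — and what passing tests therefore do not show
about real data: true CTV3 semantics and code hierarchies, comorbidity
structure, calendar seasonality, practice-level clustering, informative
visit timing unrelated to the outcome, BMI/ethnicity, and measurement
error. The pipeline's null control and signal-recovery results certify the
*machinery* (no leakage; recoverable signals are recovered), not clinical
performance.

## Numerical choices and degenerate inputs

Probability clipping ε = 1e-6 before logits; month length 30.44 days;
non-finite training loss aborts with γ and gradient-norm diagnostics;
single-class inputs to any metric or fit raise errors rather than returning
NaN; V larger than the distinct token count is clamped with a warning;
model/tensor compatibility is enforced by vocabulary hash and shape checks.

## Desk-scale experiment configuration

The end-to-end experiments run at n = 1000 patients, V = 32, k_max = 20,
5-fold CV, up to 25 epochs with patience 5 — sizes chosen so the full
battery (3 null seeds, a 3×3 signal grid, the temporal-advantage run)
completes in minutes on one CPU core. The null control uses a 30% test
fraction: a 100-patient test set would carry binomial AUROC noise of the
same order as the chance band being asserted, while 300 test patients keep
it well inside. Signal-grid AUROCs are averaged over three fixed seeds per
grid point for the same reason. The study-scale configuration (V = 512,
k_max = 200, giving the 521-predictor count with three demographics) is
exercised structurally but not trained end-to-end here.

## Known limitations

The exact layer arithmetic of the originally published TG-CNN is not
reproduced; this implementation fixes the documented contract (decay
weighting → 3D convolution → recurrent aggregation → demographic fusion →
sigmoid) and treats layer sizes as configuration. Greedy matching drops
unmatched cases rather than matching with replacement. The Wald intervals
are first-order approximations. The RNN baseline is deliberately small and
untuned, as are the count baselines — they are comparison points, not
tuned competitors.
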
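# tgehr — temporal-graph risk models for joint-replacement prediction

`tgehr` is an analysis pipeline for predicting primary hip/knee replacement
1 or 5 years in advance from coded primary-care visit streams. It is aimed
at prognostic-modelling researchers who want a fully testable, end-to-end
implementation of the temporal-graph approach: each patient's history
becomes a graph whose **nodes are clinical codes** (plus six
prescription-group tokens) and whose **edges carry the time between
consecutive visits in months**, and a convolutional network with learnable
exponential time decay turns that graph into a risk probability.

Because the primary-care records this design targets are not
distributable, the package ships a synthetic EHR generator with controlled,
known signal content. That makes the pipeline *falsifiable*: with the
signal switched off the whole chain must sit at chance (the leakage
control), with a planted signal it must recover it, and on data whose
classes differ **only** in inter-visit gap dynamics, count-based baselines
must stay at chance while the temporal model discriminates — the
mechanistic core claim that edge times carry usable signal.

## Model

For a patient with visits at distinct dates, the last `k_max` visits form
a tensor `T[k, i, j] = Δt_k` (months between visits k and k+1) for every
code pair (i at visit k, j at visit k+1); zero means no edge. The risk
model computes

    A[k,i,j] = exp(−γ · T[k,i,j])          (learnable decay γ > 0)
    A[k]    ← A[k] / |edges in slice k|     (degree normalization)
    s_t     = ReLU(Σ_f  W_f ⊛ A[t:t+d])     (3D conv filters, depth d)
    h       = RNN(s_1 … s_T)                (tanh recurrence)
    p       = σ(w·[h; age_z, sex, IMD] + b)

trained with binary cross-entropy, 5-fold CV on an exactly matched
case-control set, and post-hoc **prevalence recalibration**: a logistic GLM
of outcomes on logit(p), fitted on a held-out imbalanced slice, maps
balanced-scale probabilities back to the deployment prevalence. Evaluation
reports AUROC, AUPRC (with prevalence as the informativeness floor), the
calibration slope (C-slope; 1 = perfect), Wald 95% CIs,
PPV/sensitivity/specificity, calibration curves, and sex/IMD subgroups.

Everything numerical is NumPy with hand-derived, finite-difference-checked
gradients; standard steps (GLM fits, count-model baselines, rank metrics)
use statsmodels and scikit-learn. See `docs/methods.md` for the full
model account and design rationale.

## Worked example

```bash
python analysis/01_simulate.py        # synthetic cohort
python analysis/02_build_cohort.py    # eligibility, matching, folds
python analysis/03_coverage.py        # k_max coverage diagnostics
python analysis/04_train_evaluate.py  # TG-CNN + baselines, full metrics
python analysis/05_experiments.py     # null / recovery / temporal-advantage
```

`01_simulate.py` prints, for the default 1000-patient cohort:

```
patients: 1000  cases: 317 (31.7%)
events: 165933  visits/patient: mean 72.3, median 72
female fraction: 0.604
```

`02_build_cohort.py` shows the cohort machinery at work — 142 referral
events stripped (target-leakage guard), 59 patients excluded with logged
reasons, a 10%/10% test/calibration split and 157 exactly matched training
pairs (training prevalence 0.50, natural test prevalence 0.309).

`04_train_evaluate.py` trains all four models on identical splits and
prints one line per model, e.g.:

```
        tgcnn: AUROC 0.939 (0.876, 1.002)  AUPRC 0.909  C-slope 0.832  PPV 0.913  sens 0.724  spec 0.969  informative=True
     logistic: AUROC 0.946 (0.887, 1.005)  AUPRC 0.921  C-slope 1.033  PPV 1.000  sens 0.724  spec 1.000  informative=True
```

(AUROC/AUPRC with 95% CIs on the untouched test split; `informative=True`
means AUPRC exceeds the test prevalence. On this cohort the planted signal
lives in code *frequencies* as well as timing, so count baselines compete;
the temporal-advantage experiment below isolates timing.)

`05_experiments.py` prints the three controlled experiments:

```
null pipeline AUROC: [0.473, 0.533, 0.479] (mean 0.495; chance is 0.5)
signal 0.0: AUROC [0.464, 0.721, 0.498] (mean 0.561)
signal 1.0: AUROC [0.574, 0.812, 0.717] (mean 0.701)
signal 2.0: AUROC [0.939, 0.927, 0.92] (mean 0.929)
temporal-only signal: {'tgcnn': 0.949, 'logistic': 0.499, 'random_forest': 0.54} (count models should sit near 0.5)
```

Reading: the signal-free pipeline sits at chance (no leakage anywhere in
simulate → match → graphs → train → recalibrate → evaluate); discrimination
rises monotonically with the planted signal strength; and when the classes
share code mix and visit counts exactly, models blind to time stay at ~0.5
while the temporal-graph model reaches 0.95.

## Layout

```
src/tgehr/          library: synthetic_ehr, cohort, graph_tensor, tgcnn,
                    baselines, evaluation, pipeline, io
analysis/           numbered narrative drivers (write under results/)
tests/              pytest suite incl. brute-force oracles and the
                    end-to-end experiment battery
scripts/            acceptance.py
docs/methods.md     model account, assumptions, design decisions
```
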
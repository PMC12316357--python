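"""Discrimination, calibration and recalibration metrics for risk models.

The suite mirrors what clinical prediction-model studies report on an
imbalanced held-out set: AUROC, AUPRC (with the positive-class prevalence as
the informativeness floor), the calibration slope (C-slope) from a logistic
regression of outcomes on logit(predicted probability), Wald 95% confidence
intervals, confusion-matrix ratios at a decision threshold, equal-frequency
calibration curves, and the same block repeated per sex and IMD-quintile
subgroup.

Prevalence recalibration: a model trained on a matched (50% prevalence)
case-control set emits probabilities on the balanced scale; a logistic GLM
with logit(raw probability) as the single covariate, fitted on held-out
imbalanced data, maps them back to the deployment prevalence. The mapping is
strictly monotone whenever the fitted slope is positive, so AUROC and AUPRC
are invariant under recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

PROB_EPS = 1e-6  # clip before logit transforms

__all__ = [
    "Recalibrator",
    "MetricBlock",
    "MetricReport",
    "auroc",
    "auprc",
    "c_slope",
    "wald_ci",
    "auroc_se",
    "auprc_ci",
    "threshold_metrics",
    "calibration_curve",
    "fit_recalibrator",
    "compute_report",
    "bootstrap_compare",
]


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    return np.log(p / (1.0 - p))


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Concordance probability: P(score_case > score_control), ties counted 1/2."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, step-wise (non-interpolated).

    For a scorer independent of the labels this approaches the positive-class
    prevalence, which is why prevalence is the informativeness floor.
    """
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC requires at least one positive outcome")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def c_slope(probs: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """Calibration slope: logistic regression of outcomes on logit(probability).

    A slope of 1 indicates perfect calibration; <1 suggests the probabilities
    are too extreme (overfitting), >1 too timid. Returns (slope, se).
    """
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    x = sm.add_constant(_logit(probs))
    fit = sm.GLM(labels, x, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(fit.params)):
        raise ValueError("calibration-slope fit did not converge (separation?)")
    return float(fit.params[1]), float(fit.bse[1])


def wald_ci(point: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """point +/- z*se with z the standard-normal quantile."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    z = norm.ppf(0.5 + level / 2.0)
    return (point - z * se, point + z * se)


def auroc_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of the AUROC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auprc_ci(ap: float, n_pos: int, level: float = 0.95) -> tuple[float, float]:
    """Logit-scale Wald interval for AUPRC with effective n = number of positives."""
    ap = min(max(ap, PROB_EPS), 1.0 - PROB_EPS)
    z = norm.ppf(0.5 + level / 2.0)
    eta = np.log(ap / (1.0 - ap))
    se_eta = 1.0 / np.sqrt(n_pos * ap * (1.0 - ap))
    lo, hi = eta - z * se_eta, eta + z * se_eta
    return (float(1.0 / (1.0 + np.exp(-lo))), float(1.0 / (1.0 + np.exp(-hi))))


def threshold_metrics(
    probs: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[float, float, float]:
    """(PPV, sensitivity, specificity) for the decision rule prob >= threshold.

    PPV is reported as 0 when the rule makes no positive prediction, matching
    the reporting convention for models that flag nobody.
    """
    if not 0.0 <= threshold <= 1.0 + PROB_EPS:
        raise ValueError("threshold must lie in [0, 1]")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = probs >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    ppv = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return (float(ppv), float(sens), float(spec))


def calibration_curve(
    probs: Sequence[float], labels: Sequence[int], n_bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency calibration curve.

    Returns one row per bin with columns mean_predicted, observed_rate, n.
    Bins holding a single outcome class simply report a rate of 0 or 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(probs, kind="stable")
    edges = np.array_split(order, n_bins)
    rows = []
    for idx in edges:
        if len(idx) == 0:
            continue
        rows.append(
            {
                "mean_predicted": float(probs[idx].mean()),
                "observed_rate": float(labels[idx].mean()),
                "n": int(len(idx)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Recalibrator:
    """Logistic map from balanced-scale to prevalence-adjusted probabilities.

    recal = expit(intercept + slope * logit(raw)); strictly increasing when
    slope > 0, so rank-based metrics are unchanged by application.
    """

    intercept: float
    slope: float

    def __call__(self, raw_probs: Sequence[float]) -> np.ndarray:
        eta = self.intercept + self.slope * _logit(raw_probs)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_recalibrator(
    raw_probs: Sequence[float], labels: Sequence[int]
) -> Recalibrator:
    """Fit the prevalence recalibration GLM on out-of-sample imbalanced data."""
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    x = sm.add_constant(_logit(raw_probs))
    fit = sm.GLM(labels, x, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(fit.params)):
        raise ValueError(
            "recalibration fit did not converge "
            f"(n={len(labels)}, prevalence={labels.mean():.4f})"
        )
    return Recalibrator(intercept=float(fit.params[0]), slope=float(fit.params[1]))


@dataclass
class MetricBlock:
    """One full metric panel (overall or one subgroup)."""

    n: int
    prevalence: float
    auroc: tuple[float, float, float]
    auprc: tuple[float, float, float]
    c_slope: tuple[float, float, float]
    ppv: float
    sensitivity: float
    specificity: float
    informative: bool
    calibration_curve: list[dict]

    def to_dict(self) -> dict:
        def tripled(t):
            return {"point": t[0], "lo": t[1], "hi": t[2]}

        return {
            "n": self.n,
            "prevalence": self.prevalence,
            "auroc": tripled(self.auroc),
            "auprc": tripled(self.auprc),
            "c_slope": tripled(self.c_slope),
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "informative": self.informative,
            "calibration_curve": self.calibration_curve,
        }


@dataclass
class MetricReport:
    overall: MetricBlock
    subgroups: dict[str, MetricBlock | str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall.to_dict(),
            "subgroups": {
                k: (v if isinstance(v, str) else v.to_dict())
                for k, v in self.subgroups.items()
            },
        }


def _metric_block(
    probs: np.ndarray, labels: np.ndarray, threshold: float, n_bins: int
) -> MetricBlock:
    n = len(labels)
    prev = float(labels.mean())
    auc = auroc(probs, labels)
    ap = auprc(probs, labels)
    n_pos, n_neg = int(labels.sum()), int(n - labels.sum())
    auc_lo, auc_hi = wald_ci(auc, auroc_se(auc, n_pos, n_neg))
    ap_lo, ap_hi = auprc_ci(ap, n_pos)
    slope, slope_se = c_slope(probs, labels)
    sl_lo, sl_hi = wald_ci(slope, slope_se)
    ppv, sens, spec = threshold_metrics(probs, labels, threshold)
    curve = calibration_curve(probs, labels, n_bins=n_bins)
    return MetricBlock(
        n=n,
        prevalence=prev,
        auroc=(auc, auc_lo, auc_hi),
        auprc=(ap, ap_lo, ap_hi),
        c_slope=(slope, sl_lo, sl_hi),
        ppv=ppv,
        sensitivity=sens,
        specificity=spec,
        informative=bool(ap > prev),
        calibration_curve=curve.to_dict("records"),
    )


def compute_report(
    probs: Sequence[float],
    labels: Sequence[int],
    demographics: pd.DataFrame | None = None,
    threshold: float = 0.5,
    n_bins: int = 10,
    min_subgroup_n: int = 30,
) -> MetricReport:
    """Full metric report, overall and per sex / IMD-quintile subgroup.

    ``demographics`` needs columns ``sex`` and ``imd`` aligned with ``probs``;
    subgroups below ``min_subgroup_n`` or with one outcome class are flagged
    rather than computed.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    report = MetricReport(overall=_metric_block(probs, labels, threshold, n_bins))
    if demographics is None:
        return report
    groups: list[tuple[str, np.ndarray]] = []
    for sex in sorted(demographics["sex"].unique()):
        groups.append((f"sex={sex}", (demographics["sex"] == sex).to_numpy()))
    for q in sorted(demographics["imd"].unique()):
        groups.append((f"imd={q}", (demographics["imd"] == q).to_numpy()))
    for name, mask in groups:
        n = int(mask.sum())
        if n < min_subgroup_n:
            report.subgroups[name] = f"flagged: n={n} below floor {min_subgroup_n}"
            continue
        sub_labels = labels[mask]
        if sub_labels.min() == sub_labels.max():
            report.subgroups[name] = f"flagged: single outcome class (n={n})"
            continue
        report.subgroups[name] = _metric_block(
            probs[mask], sub_labels, threshold, n_bins
        )
    return report


def bootstrap_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    metric=auroc,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Seeded patient-level bootstrap comparison of two scorers on shared labels.

    Resamples patients with replacement, computes metric(a) - metric(b) per
    replicate, and reports the observed difference, the bootstrap 95% interval
    and a two-sided p-value (proportion of replicates crossing zero, doubled).
    """
    rng = np.random.default_rng(seed)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while labels[idx].min() == labels[idx].max():  # resample degenerate draws
            idx = rng.integers(0, n, size=n)
        diffs[b] = metric(scores_a[idx], labels[idx]) - metric(
            scores_b[idx], labels[idx]
        )
    observed = metric(scores_a, labels) - metric(scores_b, labels)
    tail = min(np.mean(diffs <= 0.0), np.mean(diffs >= 0.0))
    return {
        "difference": float(observed),
        "ci95": (float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975))),
        "p_value": float(min(1.0, 2.0 * tail)),
    }
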
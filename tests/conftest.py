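"""Shared fixtures: small synthetic corpora and brute-force metric oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tgehr.synthetic_ehr import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort reused across read-only tests."""
    config = SimConfig(n_patients=300, seed=42)
    events, patients = simulate_cohort(config)
    return config, events, patients


def auroc_bruteforce(scores, labels) -> float:
    """All-pairs concordance enumeration (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def auprc_bruteforce(scores, labels) -> float:
    """Step-wise AUPRC by explicit threshold sweep over sorted unique scores.

    Matches the non-interpolated estimator: sum over recall increments of
    the precision at that threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos = labels.sum()
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def tensor_bruteforce(visit_dates, codes_by_date, n_nodes, k_max, month_days):
    """Naive dense triple-loop temporal-tensor construction (front-padded)."""
    dates = sorted(visit_dates)[-k_max:]
    out = np.zeros((k_max - 1, n_nodes, n_nodes))
    offset = (k_max - 1) - (len(dates) - 1)
    for t in range(len(dates) - 1):
        dt = (dates[t + 1] - dates[t]).days / month_days
        for i in codes_by_date[dates[t]]:
            for j in codes_by_date[dates[t + 1]]:
                out[offset + t, i, j] = dt
    return out
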
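"""Per-patient temporal-graph representation of coded visit streams.

Each distinct visit date is a time step; clinical codes (top-V by corpus
frequency) and the six prescription-group tokens are graph nodes; the edge
between a code at visit k and a code at visit k+1 carries the elapsed time
between the two visits in months (days / 30.44). A patient becomes a sparse
3D tensor of shape (k_max - 1, N, N) with N = V + 6: slice k holds the
cross-product of codes at consecutive retained visits, every nonzero entry
equal to that visit pair's gap.

Only the last k_max visits are retained. Short histories are front-padded
(all-zero leading slices, transitions in the trailing slices) so the most
recent transition always sits at slice k_max - 2: recency occupies a fixed
tensor position for the convolution downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_ehr import PRESCRIPTION_TOKENS

MONTH_LENGTH_DAYS = 30.44  # mean Gregorian month

__all__ = [
    "GraphConfig",
    "Vocabulary",
    "TemporalGraphTensor",
    "UnrepresentablePatient",
    "build_vocabulary",
    "count_predictors",
    "build_tensor",
    "to_dense",
    "ehr_coverage",
]


class UnrepresentablePatient(ValueError):
    """Fewer than two in-vocabulary visit dates: no graph can be built."""


@dataclass(frozen=True)
class GraphConfig:
    V: int = 512
    k_max: int = 200
    month_length_days: float = MONTH_LENGTH_DAYS

    def validate(self) -> None:
        if self.V < 1:
            raise ValueError("GraphConfig.V must be at least 1")
        if self.k_max < 2:
            raise ValueError("GraphConfig.k_max must be at least 2")


@dataclass(frozen=True)
class Vocabulary:
    """Frequency-ranked node map: V clinical tokens then the 6 prescription tokens."""

    clinical_nodes: tuple[str, ...]
    coverage_fraction: float
    prescription_nodes: tuple[str, ...] = PRESCRIPTION_TOKENS

    @property
    def n_nodes(self) -> int:
        return len(self.clinical_nodes) + len(self.prescription_nodes)

    @property
    def index_of(self) -> dict[str, int]:
        nodes = self.clinical_nodes + self.prescription_nodes
        return {tok: i for i, tok in enumerate(nodes)}

    def content_hash(self) -> str:
        import hashlib

        payload = "\x1f".join(self.clinical_nodes + self.prescription_nodes)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_vocabulary(events: pd.DataFrame, V: int) -> Vocabulary:
    """Rank clinical tokens by corpus frequency (ties lexicographic), keep top V.

    Prescription nodes are always appended regardless of frequency. The
    coverage fraction is the share of clinical events the V retained tokens
    account for.
    """
    if len(events) == 0:
        raise ValueError("cannot build a vocabulary from an empty event table")
    clinical = events[events["source"] == "clinical"]
    counts = clinical["code"].value_counts()
    n_distinct = len(counts)
    if V > n_distinct:
        warnings.warn(
            f"V={V} exceeds the {n_distinct} distinct clinical tokens; clamping",
            stacklevel=2,
        )
        V = n_distinct
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:V]
    covered = sum(c for _, c in top)
    return Vocabulary(
        clinical_nodes=tuple(tok for tok, _ in top),
        coverage_fraction=covered / len(clinical) if len(clinical) else 0.0,
    )


def count_predictors(vocabulary: Vocabulary, n_demographics: int) -> int:
    """Total predictor count: V clinical + 6 prescription nodes + demographics."""
    return vocabulary.n_nodes + n_demographics


@dataclass(frozen=True)
class TemporalGraphTensor:
    """Sparse per-patient tensor: quadruples (slice k, source i, target j, dt months)."""

    patient_id: str
    entries: np.ndarray  # shape (m, 4): columns k, i, j (ints as float), dt
    n_visits_used: int
    n_oov_dropped: int
    shape: tuple[int, int, int]  # (k_max - 1, N, N)

    def __post_init__(self):
        object.__setattr__(
            self, "entries", np.asarray(self.entries, dtype=float).reshape(-1, 4)
        )


def build_tensor(
    patient_events: pd.DataFrame,
    vocabulary: Vocabulary,
    config: GraphConfig,
) -> TemporalGraphTensor:
    """Turn one patient's (censored) events into the sparse temporal tensor.

    Visits are sorted distinct dates; out-of-vocabulary codes are dropped
    (counted); only the last k_max visits are kept; consecutive visit pairs
    contribute cross-product edges carrying the pair's gap in months.
    """
    config.validate()
    index = vocabulary.index_of
    ev = patient_events
    in_vocab = ev["code"].isin(index)
    n_oov = int((~in_vocab).sum())
    ev = ev.loc[in_vocab]
    pid = str(patient_events["patient_id"].iloc[0]) if len(patient_events) else "?"

    by_date: dict[pd.Timestamp, set[int]] = {}
    for d, code in zip(ev["date"], ev["code"]):
        by_date.setdefault(pd.Timestamp(d), set()).add(index[code])
    dates = sorted(by_date)
    if len(dates) < 2:
        raise UnrepresentablePatient(
            f"patient {pid}: {len(dates)} in-vocabulary visit date(s); need >= 2"
        )
    dates = dates[-config.k_max :]
    n_used = len(dates)
    n_slices = config.k_max - 1
    offset = n_slices - (n_used - 1)  # front padding: data occupies trailing slices

    quads = []
    for t in range(n_used - 1):
        d0, d1 = dates[t], dates[t + 1]
        dt_months = (d1 - d0).days / config.month_length_days
        k = offset + t
        for i in sorted(by_date[d0]):
            for j in sorted(by_date[d1]):
                quads.append((k, i, j, dt_months))
    N = vocabulary.n_nodes
    return TemporalGraphTensor(
        patient_id=pid,
        entries=np.array(quads, dtype=float),
        n_visits_used=n_used,
        n_oov_dropped=n_oov,
        shape=(n_slices, N, N),
    )


def to_dense(tensor: TemporalGraphTensor) -> np.ndarray:
    """Densify the sparse quadruples into the full (k_max-1, N, N) array."""
    out = np.zeros(tensor.shape, dtype=float)
    if len(tensor.entries):
        k = tensor.entries[:, 0].astype(int)
        i = tensor.entries[:, 1].astype(int)
        j = tensor.entries[:, 2].astype(int)
        out[k, i, j] = tensor.entries[:, 3]
    return out


def ehr_coverage(patient_events: pd.DataFrame, k_max: int) -> float:
    """Fraction of a patient's record timespan covered by the last k_max visits.

    Patients with at most k_max visits (and single-visit patients, by
    convention) are fully covered.
    """
    dates = sorted(pd.to_datetime(patient_events["date"]).unique())
    if len(dates) == 0:
        raise ValueError("patient has no visits")
    if len(dates) <= k_max or len(dates) == 1:
        return 1.0
    total = (dates[-1] - dates[0]).days
    if total == 0:
        return 1.0
    covered = (dates[-1] - dates[-k_max]).days
    return covered / total
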
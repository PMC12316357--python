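"""Cohort assembly: outcome labelling, eligibility, splitting and matching.

Cases are patients whose record carries a primary-replacement token; the
index date is the FIRST occurrence of such a token. Controls receive a
seeded reference date drawn from the empirical distribution of case index
dates so their histories are censored comparably (avoids immortal-time
bias). Features downstream may only use events up to the censor date
(index/reference date minus the prediction horizon).

Eligibility: age 40-75 at the window start, at least two distinct visit
dates inside the horizon-length window before the index/reference date, no
revision/modification code preceding a primary code, and no revision-only
controls. Replacement-related hospital referral codes are stripped from the
event stream before anything downstream sees it (target-leakage guard).

Splitting follows the case-control design: a seeded uniform 10% test split
retaining natural imbalance, a held-out imbalanced calibration slice for the
prevalence recalibrator, and a training remainder in which every case is
exactly matched (integer age, sex, IMD quintile) to one unused control via a
seeded-shuffle greedy pass. With an exact 3-way key, greedy attains the
maximum matching within each key group, so no assignment machinery is
needed. Matched pairs are co-assigned to cross-validation folds.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_ehr import (
    PRIMARY_TOKEN,
    REFERRAL_TOKEN,
    REVISION_TOKEN,
    WINDOW_START,
)

__all__ = [
    "CohortConfig",
    "OutcomeTokens",
    "apply_inclusion",
    "strip_leakage_codes",
    "split_and_match",
    "make_folds",
    "build_cohort",
]


@dataclass(frozen=True)
class OutcomeTokens:
    """Token sets identifying the outcome and its leakage-prone satellites."""

    primary: frozenset = frozenset({PRIMARY_TOKEN})
    revision: frozenset = frozenset({REVISION_TOKEN})
    referral: frozenset = frozenset({REFERRAL_TOKEN})

    def validate(self) -> None:
        if not self.primary or not self.revision or not self.referral:
            raise ValueError("outcome token sets must all be non-empty")


@dataclass(frozen=True)
class CohortConfig:
    horizon_years: int = 1
    joint: str = "hip"
    test_fraction: float = 0.10
    calib_fraction: float = 0.10
    n_folds: int = 5
    min_visits_in_window: int = 2
    age_range: tuple[int, int] = (40, 75)
    window_start: dt.date = WINDOW_START
    seed: int = 0
    tokens: OutcomeTokens = field(default_factory=OutcomeTokens)

    def validate(self) -> None:
        if self.horizon_years not in (1, 5):
            raise ValueError("CohortConfig.horizon_years must be 1 or 5")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("CohortConfig.test_fraction must lie in (0, 1)")
        if not 0.0 <= self.calib_fraction < 1.0:
            raise ValueError("CohortConfig.calib_fraction must lie in [0, 1)")
        if self.n_folds < 2:
            raise ValueError("CohortConfig.n_folds must be at least 2")
        if self.joint not in ("hip", "knee"):
            raise ValueError("CohortConfig.joint must be 'hip' or 'knee'")
        self.tokens.validate()


def strip_leakage_codes(
    events: pd.DataFrame, referral_tokens
) -> tuple[pd.DataFrame, int]:
    """Drop replacement-referral codes from the stream; returns (events, n_removed)."""
    referral_tokens = set(referral_tokens)
    if not referral_tokens:
        raise ValueError("referral token set must be non-empty")
    mask = events["code"].isin(referral_tokens)
    return events.loc[~mask].reset_index(drop=True), int(mask.sum())


def _first_token_date(events: pd.DataFrame, tokens) -> pd.Series:
    hits = events[events["code"].isin(set(tokens))]
    return hits.groupby("patient_id")["date"].min()


def apply_inclusion(
    events: pd.DataFrame, patients: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label outcomes, assign index/censor dates and apply eligibility rules.

    Returns ``(eligible, exclusion_log)``. ``eligible`` has one row per
    retained patient with columns label, index_date, censor_date plus the
    demographics; ``exclusion_log`` records one (patient_id, reason) row per
    removed patient, with reasons applied in the fixed order
    age -> revision_before_primary -> revision_without_primary ->
    insufficient_visits.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    horizon = pd.Timedelta(days=round(config.horizon_years * 365.25))

    first_primary = _first_token_date(events, config.tokens.primary)
    first_revision = _first_token_date(events, config.tokens.revision)
    plain = events[
        ~events["code"].isin(config.tokens.primary | config.tokens.revision)
    ]
    visit_dates = {
        pid: np.array(sorted(s.unique()))
        for pid, s in plain.groupby("patient_id")["date"]
    }

    case_index_dates = first_primary.to_numpy()
    if len(case_index_dates) == 0:
        raise ValueError("no primary-replacement token found in the event stream")

    rows, excluded = [], []
    for p in patients.itertuples(index=False):
        pid = p.patient_id
        is_case = pid in first_primary.index
        lo, hi = config.age_range
        if not lo <= p.age_at_start <= hi:
            excluded.append((pid, "age"))
            continue
        if is_case:
            index_date = first_primary[pid]
            if pid in first_revision.index and first_revision[pid] < index_date:
                excluded.append((pid, "revision_before_primary"))
                continue
        else:
            if pid in first_revision.index:
                excluded.append((pid, "revision_without_primary"))
                continue
            index_date = pd.Timestamp(rng.choice(case_index_dates))
        dates = visit_dates.get(pid, np.array([], dtype="datetime64[ns]"))
        in_window = [
            d for d in np.atleast_1d(dates) if index_date - horizon <= d < index_date
        ]
        if len(in_window) < config.min_visits_in_window:
            excluded.append((pid, "insufficient_visits"))
            continue
        rows.append(
            {
                "patient_id": pid,
                "label": "case" if is_case else "control",
                "index_date": index_date,
                "censor_date": index_date - horizon,
                "age_at_start": p.age_at_start,
                "sex": p.sex,
                "imd": p.imd,
            }
        )
    eligible = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "label",
            "index_date",
            "censor_date",
            "age_at_start",
            "sex",
            "imd",
        ],
    )
    log = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return eligible, log


def censor_events(events: pd.DataFrame, eligible: pd.DataFrame) -> pd.DataFrame:
    """Keep only events strictly before each patient's censor date.

    This is the leakage guard every downstream feature builder relies on.
    """
    censor = eligible.set_index("patient_id")["censor_date"]
    ev = events[events["patient_id"].isin(censor.index)].copy()
    keep = ev["date"].to_numpy() < censor.loc[ev["patient_id"]].to_numpy()
    out = ev.loc[keep].reset_index(drop=True)
    # programmatic assertion of the leakage invariant
    if len(out):
        latest = out.groupby("patient_id")["date"].max()
        assert (latest < censor.loc[latest.index]).all(), "leakage invariant violated"
    return out


def split_and_match(eligible: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Seeded test/calibration split plus greedy exact 1:1 matching in training.

    Returns the cohort table: columns patient_id, label, index_date,
    censor_date, split (train/calib/test), fold (NaN outside train),
    matched_to (partner patient_id for matched pairs). Unmatched cases are
    dropped; unmatched controls are simply not part of the training set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    ids = eligible["patient_id"].to_numpy()
    n = len(ids)
    order = rng.permutation(n)
    n_test = int(round(config.test_fraction * n))
    n_calib = int(round(config.calib_fraction * n))
    test_ids = set(ids[order[:n_test]])
    calib_ids = set(ids[order[n_test : n_test + n_calib]])

    table = eligible.copy()
    table["split"] = [
        "test" if i in test_ids else ("calib" if i in calib_ids else "train")
        for i in table["patient_id"]
    ]
    table["matched_to"] = pd.NA
    table["fold"] = pd.NA

    train = table[table["split"] == "train"]
    cases = train[train["label"] == "case"]
    controls = train[train["label"] == "control"]

    # greedy matching within exact (age, sex, imd) key groups, seeded order
    pool: dict[tuple, list[str]] = {}
    for c in controls.sample(frac=1.0, random_state=int(rng.integers(2**31))).itertuples():
        pool.setdefault((c.age_at_start, c.sex, c.imd), []).append(c.patient_id)
    matched_to: dict[str, str] = {}
    dropped_cases: list[str] = []
    case_order = cases.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    for c in case_order.itertuples():
        key = (c.age_at_start, c.sex, c.imd)
        bucket = pool.get(key)
        if bucket:
            partner = bucket.pop()
            matched_to[c.patient_id] = partner
            matched_to[partner] = c.patient_id
        else:
            dropped_cases.append(c.patient_id)

    if not matched_to:
        raise ValueError("no matched training set: zero matchable case-control pairs")

    keep_train = set(matched_to)
    keep = table["split"].isin(["test", "calib"]) | table["patient_id"].isin(keep_train)
    table = table.loc[keep].reset_index(drop=True)
    table["matched_to"] = table["patient_id"].map(matched_to)
    table.attrs["dropped_unmatched_cases"] = dropped_cases
    return table


def make_folds(cohort: pd.DataFrame, n_folds: int, seed: int) -> pd.DataFrame:
    """Assign matched training pairs to folds; pair members share a fold.

    Fold sizes (in pairs) differ by at most one.
    """
    train = cohort[cohort["split"] == "train"]
    pairs = sorted(
        tuple(sorted((r.patient_id, r.matched_to)))
        for r in train.itertuples()
        if r.label == "case"
    )
    if not pairs:
        raise ValueError("no matched pairs to fold")
    if n_folds > len(pairs):
        raise ValueError(f"n_folds={n_folds} exceeds number of pairs ({len(pairs)})")
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(len(pairs))
    fold_of: dict[str, int] = {}
    for rank, pair_idx in enumerate(order):
        f = rank % n_folds + 1
        a, b = pairs[pair_idx]
        fold_of[a] = f
        fold_of[b] = f
    out = cohort.copy()
    out["fold"] = out["patient_id"].map(fold_of).astype("Int64")
    return out


def build_cohort(
    events: pd.DataFrame, patients: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, int]:
    """Leakage-strip, include, split, match, fold: the full cohort pass.

    Returns (cohort, censored_events, exclusion_log, n_leakage_removed).
    """
    clean, n_removed = strip_leakage_codes(events, config.tokens.referral)
    eligible, log = apply_inclusion(clean, patients, config)
    table = split_and_match(eligible, config)
    table = make_folds(table, config.n_folds, config.seed)
    feature_events = censor_events(
        clean[~clean["code"].isin(config.tokens.primary | config.tokens.revision)],
        table,
    )
    return table, feature_events, log, n_removed
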
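"""Synthetic primary-care event streams with a joint-replacement outcome.

Emulates the statistical structure of UK primary-care coded records over a
15-year observation window (a 1999-2014 analogue): patients aged 40-75 at the
window start, ~62% female, visit frequency graded by IMD quintile, up to 10
clinical codes per visit, a heavy-tailed (Zipf) rank-frequency law over the
clinical vocabulary, six prescription-group tokens (opioids / non-opioid
analgesics / NSAIDs, each acute or repeat), and a minority-class replacement
outcome whose precursor-code and prescription intensity ramps up as the
replacement date approaches.

Two signal mechanisms are available:

* default: an inhomogeneous Poisson visit process for cases whose rate and
  precursor-code mixture weight ramp linearly over the final 2 x horizon
  years before replacement, scaled by ``signal_strength``;
* ``temporal_signal_only``: both classes share the visit-count distribution
  and the code mixture; only inter-visit gap dynamics differ (case gaps
  shrink geometrically toward the censor date), so any count-based
  representation is uninformative by construction while edge times carry
  the entire signal.

A small fraction of patients carries revision-before-primary or
revision-without-primary code patterns, plus pre-replacement hospital
referral codes, so the downstream exclusion and leakage-stripping rules are
exercised on realistic input.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# The six prescription-group tokens: 3 BNF drug groups x {acute, repeat}.
PRESCRIPTION_TOKENS = (
    "RX_NOA_ACUTE",
    "RX_NOA_REPEAT",
    "RX_OPIOID_ACUTE",
    "RX_OPIOID_REPEAT",
    "RX_NSAID_ACUTE",
    "RX_NSAID_REPEAT",
)

WINDOW_START = dt.date(1999, 4, 1)

# Outcome / leakage tokens understood by the cohort module.
PRIMARY_TOKEN = "XP_PRIMARY_REPLACEMENT"
REVISION_TOKEN = "XR_REVISION_REPLACEMENT"
REFERRAL_TOKEN = "XF_REFERRAL_REPLACEMENT"

# Ranks (0-based) of the background Zipf law designated as pain precursors.
_PAIN_RANKS = range(10, 20)

# Rates for the rule-exercising corner patterns (fractions of patients).
_REVISION_AFTER_PRIMARY_RATE = 0.05   # legitimate cases, retained downstream
_REVISION_BEFORE_PRIMARY_RATE = 0.01  # cases that must be excluded
_REVISION_ONLY_CONTROL_RATE = 0.01    # controls that must be excluded


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study conditions."""

    n_patients: int = 1000
    vocab_pool_size: int = 2000
    target_prevalence: float = 0.30
    horizon_years: int = 1
    window_years: float = 15.0
    age_range: tuple[int, int] = (40, 75)
    female_fraction: float = 0.62
    # mean visits over the window by IMD quintile; endpoints follow the
    # reported 54.6 (most deprived) to 82.9 (least deprived) gradient
    imd_visit_rate_gradient: dict[int, float] = field(
        default_factory=lambda: {1: 54.6, 2: 61.7, 3: 68.8, 4: 75.8, 5: 82.9}
    )
    signal_strength: float = 1.0
    max_codes_per_visit: int = 10
    zipf_exponent: float = 1.4
    mean_codes_per_visit: float = 1.5
    temporal_signal_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("SimConfig.n_patients must be nonnegative")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("SimConfig.target_prevalence must lie strictly in (0, 1)")
        lo, hi = self.age_range
        if not (18 <= lo < hi <= 120):
            raise ValueError("SimConfig.age_range must satisfy 18 <= low < high <= 120")
        if self.horizon_years not in (1, 5):
            raise ValueError("SimConfig.horizon_years must be 1 or 5")
        if self.vocab_pool_size < 1:
            raise ValueError("SimConfig.vocab_pool_size must be positive")
        if self.max_codes_per_visit < 1:
            raise ValueError("SimConfig.max_codes_per_visit must be positive")
        if self.signal_strength < 0:
            raise ValueError("SimConfig.signal_strength must be nonnegative")
        if self.window_years <= 0:
            raise ValueError("SimConfig.window_years must be positive")
        if sorted(self.imd_visit_rate_gradient) != [1, 2, 3, 4, 5]:
            raise ValueError("SimConfig.imd_visit_rate_gradient needs quintiles 1..5")
        rates = [self.imd_visit_rate_gradient[q] for q in (1, 2, 3, 4, 5)]
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ValueError("SimConfig.imd_visit_rate_gradient must be monotone")


def clinical_token(rank: int) -> str:
    """Token for the clinical code of a given Zipf rank (0-based)."""
    return f"C{rank:04d}"


def _zipf_probs(pool: int, exponent: float) -> np.ndarray:
    w = np.arange(1, pool + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _date(day_offset: float) -> dt.date:
    return WINDOW_START + dt.timedelta(days=int(round(day_offset)))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the event stream and patient ground truth.

    Returns ``(events, patients)``:

    * events: columns patient_id, date, code, source (clinical/prescription);
    * patients: columns patient_id, age_at_start, sex, imd, replacement_date
      (NaT for controls) and latent_severity_trajectory (per-visit severity,
      exported for parameter-recovery tests).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    window_days = config.window_years * 365.25
    horizon_days = config.horizon_years * 365.25
    probs = _zipf_probs(config.vocab_pool_size, config.zipf_exponent)
    cum_probs = np.cumsum(probs)
    pain_pool = np.array([r for r in _PAIN_RANKS if r < config.vocab_pool_size])

    event_rows: list[tuple[str, dt.date, str, str]] = []
    patient_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        sex = "female" if rng.random() < config.female_fraction else "male"
        imd = int(rng.integers(1, 6))
        is_case = bool(rng.random() < config.target_prevalence)

        if config.temporal_signal_only:
            visit_days, severities, replacement_day = _temporal_only_patient(
                rng, config, imd, is_case, window_days, horizon_days
            )
        else:
            visit_days, severities, replacement_day = _ramp_patient(
                rng, config, imd, is_case, window_days, horizon_days
            )

        for day, sev in zip(visit_days, severities):
            date = _date(day)
            n_codes = 1 + rng.poisson(config.mean_codes_per_visit)
            n_codes = min(n_codes, config.max_codes_per_visit)
            emitted: set[str] = set()
            for _ in range(n_codes):
                if (
                    not config.temporal_signal_only
                    and sev > 0
                    and rng.random() < min(0.9, sev)
                ):
                    rank = int(pain_pool[rng.integers(len(pain_pool))])
                else:
                    rank = int(np.searchsorted(cum_probs, rng.random()))
                emitted.add(clinical_token(rank))
            for tok in sorted(emitted):
                event_rows.append((pid, date, tok, "clinical"))
            # prescriptions ride on painful visits; base rate keeps the six
            # tokens present among controls too
            rx_p = 0.05 + (0.0 if config.temporal_signal_only else 0.6 * min(1.0, sev))
            if rng.random() < rx_p:
                tok = PRESCRIPTION_TOKENS[int(rng.integers(len(PRESCRIPTION_TOKENS)))]
                event_rows.append((pid, date, tok, "prescription"))

        replacement_date = None
        if is_case and replacement_day is not None:
            replacement_date = _date(replacement_day)
            event_rows.append((pid, replacement_date, PRIMARY_TOKEN, "clinical"))
            u = rng.random()
            if u < _REVISION_BEFORE_PRIMARY_RATE:
                # corner pattern: revision precedes primary -> excluded later
                bad_day = max(0.0, replacement_day - rng.uniform(200, 800))
                event_rows.append((pid, _date(bad_day), REVISION_TOKEN, "clinical"))
            elif u < _REVISION_BEFORE_PRIMARY_RATE + _REVISION_AFTER_PRIMARY_RATE:
                rev_day = min(window_days, replacement_day + rng.uniform(100, 600))
                event_rows.append((pid, _date(rev_day), REVISION_TOKEN, "clinical"))
            # leakage pattern: a hospital referral code shortly before surgery
            if rng.random() < 0.5:
                ref_day = max(0.0, replacement_day - rng.uniform(30, 180))
                event_rows.append((pid, _date(ref_day), REFERRAL_TOKEN, "clinical"))
        elif not is_case and rng.random() < _REVISION_ONLY_CONTROL_RATE:
            rev_day = rng.uniform(0.3, 1.0) * window_days
            event_rows.append((pid, _date(rev_day), REVISION_TOKEN, "clinical"))

        patient_rows.append(
            {
                "patient_id": pid,
                "age_at_start": age,
                "sex": sex,
                "imd": imd,
                "replacement_date": pd.Timestamp(replacement_date)
                if replacement_date
                else pd.NaT,
                "latent_severity_trajectory": np.asarray(severities, dtype=float),
            }
        )

    events = pd.DataFrame(
        event_rows, columns=["patient_id", "date", "code", "source"]
    )
    if len(events):
        events["date"] = pd.to_datetime(events["date"])
        events = events.sort_values(
            ["patient_id", "date", "source", "code"], kind="stable"
        ).reset_index(drop=True)
    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id",
            "age_at_start",
            "sex",
            "imd",
            "replacement_date",
            "latent_severity_trajectory",
        ],
    )
    return events, patients


def _ramp_patient(rng, config, imd, is_case, window_days, horizon_days):
    """Default mechanism: baseline visits plus a linear case ramp."""
    base_rate = config.imd_visit_rate_gradient[imd]
    n_base = rng.poisson(base_rate)
    visit_days = list(rng.uniform(0.0, window_days, size=n_base))
    severities = [0.0] * n_base
    replacement_day = None
    if is_case:
        ramp_len = min(2.0 * horizon_days, window_days * 0.6)
        replacement_day = rng.uniform(ramp_len + 0.1 * window_days, window_days)
        # extra visits from the linearly rising pre-replacement intensity
        n_extra = rng.poisson(config.signal_strength * 6.0)
        for _ in range(n_extra):
            # density ~ u on [0,1] mapped to the ramp; recent times favoured
            frac = np.sqrt(rng.random())
            visit_days.append(replacement_day - ramp_len * (1.0 - frac))
            severities.append(0.0)
        for k, day in enumerate(visit_days):
            into_ramp = (day - (replacement_day - ramp_len)) / ramp_len
            if 0.0 < into_ramp <= 1.0:
                severities[k] = config.signal_strength * into_ramp
    order = np.argsort(visit_days, kind="stable")
    visit_days = [visit_days[k] for k in order]
    severities = [severities[k] for k in order]
    # collapse same-calendar-day duplicates; keep the larger severity
    merged: dict[int, float] = {}
    for day, sev in zip(visit_days, severities):
        key = int(round(day))
        merged[key] = max(merged.get(key, 0.0), sev)
    days = sorted(merged)
    return [float(d) for d in days], [merged[d] for d in days], replacement_day


def _temporal_only_patient(rng, config, imd, is_case, window_days, horizon_days):
    """Classes share counts and code mix; only inter-visit gaps differ.

    Both classes receive the same Poisson visit count and an index date near
    the window end; control visits are uniform over the pre-censor span while
    case gaps decay geometrically toward the censor date.
    """
    base_rate = config.imd_visit_rate_gradient[imd]
    n_visits = max(3, rng.poisson(base_rate))
    replacement_day = window_days - rng.uniform(0.0, 30.0)
    censor_day = replacement_day - horizon_days
    span = censor_day - 1.0
    # both classes: n_visits dates from day 0 to the eve of censoring, gaps
    # floored at 1.5 days so rounding to calendar days never merges visits
    # (merging would leak the class into the visit count)
    n_gaps = n_visits - 1
    w = rng.gamma(1.0, size=n_gaps)
    if is_case:
        # gap sizes biased to shrink toward the censor date; strength sets
        # the old-to-recent expected gap ratio exp(signal_strength)
        w = w * np.exp(config.signal_strength * np.arange(n_gaps, 0, -1) / n_gaps)
    gaps = 1.5 + (span - 1.5 * n_gaps) * w / w.sum()
    days = np.concatenate([[0.0], np.cumsum(gaps)])
    # both classes get identically distributed visits inside the horizon
    # window (post-censor, so invisible to features but satisfying the
    # two-visits eligibility rule)
    recent = censor_day + rng.uniform(0.05, 0.95, size=2) * (
        replacement_day - censor_day - 1.0
    )
    days = np.concatenate([days, recent])
    merged = sorted({int(round(d)) for d in days if d >= 0})
    severities = [0.0] * len(merged)
    return (
        [float(d) for d in merged],
        severities,
        replacement_day if is_case else None,
    )
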
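"""Assemble the analysis cohort: eligibility, leakage stripping, matching.

Reads results/events.csv and results/patients.csv, applies the inclusion
rules (age 40-75, two visits in the pre-index horizon window, revision and
referral exclusions), draws the 10% test and 10% calibration splits, exactly
matches training cases to controls on (age, sex, IMD), and co-assigns
matched pairs to cross-validation folds.

Writes results/cohort.csv and results/exclusions.csv.
"""

import argparse
from pathlib import Path

from tgehr import io
from tgehr.cohort import CohortConfig, build_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--horizon-years", type=int, default=1, choices=(1, 5))
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    events = io.read_events(args.dir / "events.csv")
    patients = io.read_patients(args.dir / "patients.csv")
    config = CohortConfig(horizon_years=args.horizon_years, seed=args.seed)
    cohort, feature_events, log, n_leak = build_cohort(events, patients, config)

    io.write_cohort(cohort, args.dir / "cohort.csv")
    log.to_csv(args.dir / "exclusions.csv", index=False)

    print(f"leakage-stripped referral events: {n_leak}")
    print("exclusions:", dict(log["reason"].value_counts()))
    print("splits:", dict(cohort["split"].value_counts()))
    train = cohort[cohort["split"] == "train"]
    print(f"matched training pairs: {(train['label'] == 'case').sum()} "
          f"(prevalence {(train['label'] == 'case').mean():.2f})")
    test = cohort[cohort["split"] == "test"]
    print(f"test prevalence (natural): {(test['label'] == 'case').mean():.3f}")
    print(f"wrote {args.dir}/cohort.csv and {args.dir}/exclusions.csv")


if __name__ == "__main__":
    main()
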
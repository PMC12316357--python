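"""Cohort assembly: eligibility rules, leakage stripping, matching, folds."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tgehr.cohort import (
    CohortConfig,
    apply_inclusion,
    censor_events,
    make_folds,
    split_and_match,
    strip_leakage_codes,
)
from tgehr.synthetic_ehr import PRIMARY_TOKEN, REFERRAL_TOKEN, REVISION_TOKEN


def _events(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "code", "source"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def _patients(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "age_at_start", "sex", "imd"]
    )


def _visit_rows(pid, dates, code="C0001"):
    return [(pid, d, code, "clinical") for d in dates]


class TestLeakageStripping:
    def test_referral_rows_removed_and_counted(self):
        ev = _events(
            _visit_rows("A", ["2001-01-01", "2001-02-01"])
            + [("A", "2001-03-01", REFERRAL_TOKEN, "clinical")] * 3
        )
        out, n = strip_leakage_codes(ev, {REFERRAL_TOKEN})
        assert n == 3
        assert len(out) == len(ev) - 3
        assert not out["code"].isin({REFERRAL_TOKEN}).any()

    def test_empty_referral_set_rejected(self):
        with pytest.raises(ValueError):
            strip_leakage_codes(_events([]), set())

    def test_no_referral_rows_is_identity(self):
        ev = _events(_visit_rows("A", ["2001-01-01", "2001-02-01"]))
        out, n = strip_leakage_codes(ev, {REFERRAL_TOKEN})
        assert n == 0
        pd.testing.assert_frame_equal(out, ev)


class TestInclusion:
    CFG = CohortConfig(horizon_years=1, seed=0)

    def test_single_visit_in_window_excluded(self):
        # case with replacement 2005-06-01; only one visit in the prior year
        ev = _events(
            _visit_rows("A", ["2004-09-01"])
            + [("A", "2005-06-01", PRIMARY_TOKEN, "clinical")]
            # an anchor case so controls can draw reference dates
            + _visit_rows("B", ["2004-08-01", "2004-12-01"])
            + [("B", "2005-05-01", PRIMARY_TOKEN, "clinical")]
        )
        pats = _patients([("A", 60, "female", 3), ("B", 61, "male", 2)])
        eligible, log = apply_inclusion(ev, pats, self.CFG)
        assert log.set_index("patient_id").loc["A", "reason"] == "insufficient_visits"
        assert "B" in set(eligible["patient_id"])

    def test_age_boundary_below_40_excluded(self):
        ev = _events(
            _visit_rows("A", ["2004-08-01", "2004-12-01"])
            + [("A", "2005-05-01", PRIMARY_TOKEN, "clinical")]
            + _visit_rows("B", ["2004-08-01", "2004-12-01"])
            + [("B", "2005-05-01", PRIMARY_TOKEN, "clinical")]
        )
        pats = _patients([("A", 39, "female", 3), ("B", 40, "male", 1)])
        eligible, log = apply_inclusion(ev, pats, self.CFG)
        assert log.set_index("patient_id").loc["A", "reason"] == "age"
        assert set(eligible["patient_id"]) == {"B"}

    def test_eight_patient_toy_cohort_rule_by_rule(self):
        """Brute-force manual application of every rule on 8 patients."""
        rows = []
        pats = []
        # P1: clean case
        rows += _visit_rows("P1", ["2004-07-01", "2005-01-10"])
        rows += [("P1", "2005-06-01", PRIMARY_TOKEN, "clinical")]
        pats.append(("P1", 55, "female", 2))
        # P2: revision BEFORE primary -> excluded
        rows += _visit_rows("P2", ["2004-07-01", "2005-01-10"])
        rows += [
            ("P2", "2004-01-01", REVISION_TOKEN, "clinical"),
            ("P2", "2005-06-01", PRIMARY_TOKEN, "clinical"),
        ]
        pats.append(("P2", 60, "male", 3))
        # P3: revision AFTER primary -> retained as case
        rows += _visit_rows("P3", ["2004-08-01", "2005-02-01"])
        rows += [
            ("P3", "2005-06-01", PRIMARY_TOKEN, "clinical"),
            ("P3", "2006-01-01", REVISION_TOKEN, "clinical"),
        ]
        pats.append(("P3", 65, "female", 4))
        # P4: revision-only control -> excluded
        rows += _visit_rows("P4", ["2004-07-01", "2005-01-10", "2005-03-01"])
        rows += [("P4", "2005-09-01", REVISION_TOKEN, "clinical")]
        pats.append(("P4", 50, "male", 1))
        # P5, P6: clean controls with plenty of visits
        for pid in ("P5", "P6"):
            rows += _visit_rows(
                pid,
                pd.date_range("2004-01-01", "2005-12-01", freq="MS").strftime(
                    "%Y-%m-%d"
                ),
            )
            pats.append((pid, 58, "female", 2))
        # P7: control, too old at window start
        rows += _visit_rows("P7", ["2004-07-01", "2005-01-10"])
        pats.append(("P7", 80, "male", 5))
        # P8: clean case
        rows += _visit_rows("P8", ["2004-05-01", "2004-11-15"])
        rows += [("P8", "2005-04-01", PRIMARY_TOKEN, "clinical")]
        pats.append(("P8", 47, "male", 5))

        eligible, log = apply_inclusion(_events(rows), _patients(pats), self.CFG)
        log = log.set_index("patient_id")["reason"]
        assert log.loc["P2"] == "revision_before_primary"
        assert log.loc["P4"] == "revision_without_primary"
        assert log.loc["P7"] == "age"
        kept = eligible.set_index("patient_id")
        assert set(kept.index) >= {"P1", "P3", "P8"}
        assert (kept.loc[["P1", "P3", "P8"], "label"] == "case").all()
        # index date is the FIRST primary token date
        assert kept.loc["P1", "index_date"] == pd.Timestamp("2005-06-01")
        assert kept.loc["P8", "censor_date"] == pd.Timestamp("2005-04-01") - pd.Timedelta(days=365)

    def test_censoring_removes_all_post_censor_events(self):
        ev = _events(
            _visit_rows("A", ["2004-07-01", "2005-01-10", "2005-05-20"])
            + [("A", "2005-06-01", PRIMARY_TOKEN, "clinical")]
        )
        pats = _patients([("A", 60, "female", 3)])
        eligible, _ = apply_inclusion(ev, pats, self.CFG)
        out = censor_events(ev, eligible)
        censor = eligible.iloc[0]["censor_date"]
        assert (out["date"] < censor).all()


def brute_force_max_matching(cases, controls):
    """Maximum exact matching size: sum over keys of min(#cases, #controls)."""
    from collections import Counter

    ck = Counter(cases)
    nk = Counter(controls)
    return sum(min(ck[k], nk[k]) for k in ck)


class TestMatching:
    def _table(self, rows):
        df = pd.DataFrame(
            rows, columns=["patient_id", "label", "age_at_start", "sex", "imd"]
        )
        df["index_date"] = pd.Timestamp("2005-01-01")
        df["censor_date"] = pd.Timestamp("2004-01-01")
        return df

    def test_spec_toy_case(self):
        """Case with two exact controls matches one; unmatched case dropped."""
        rows = [
            ("c1", "case", 60, "female", 3),
            ("c2", "case", 70, "male", 1),
            ("k1", "control", 60, "female", 3),
            ("k2", "control", 60, "female", 3),
            ("k3", "control", 71, "male", 1),
        ]
        cfg = CohortConfig(test_fraction=0.01, calib_fraction=0.0, seed=0)
        table = split_and_match(self._table(rows), cfg)
        train = table[table["split"] == "train"]
        matched_cases = train[train["label"] == "case"]
        assert list(matched_cases["patient_id"]) == ["c1"]
        partner = matched_cases.iloc[0]["matched_to"]
        assert partner in {"k1", "k2"}
        assert "c2" in table.attrs["dropped_unmatched_cases"]

    def test_matched_training_prevalence_exactly_half(self, small_cohort):
        from tgehr.cohort import build_cohort

        _, events, patients = small_cohort
        table, _, _, _ = build_cohort(events, patients, CohortConfig(seed=1))
        train = table[table["split"] == "train"]
        assert (train["label"] == "case").mean() == 0.5

    def test_matching_invariants_and_determinism(self, small_cohort):
        from tgehr.cohort import build_cohort

        _, events, patients = small_cohort
        cfg = CohortConfig(seed=2)
        t1, _, _, _ = build_cohort(events, patients, cfg)
        t2, _, _, _ = build_cohort(events, patients, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        train = t1[t1["split"] == "train"].set_index("patient_id")
        for pid, row in train.iterrows():
            partner = train.loc[row["matched_to"]]
            assert partner["matched_to"] == pid  # symmetric, used once
            for col in ("age_at_start", "sex", "imd"):
                assert partner[col] == row[col]
        assert not set(train.index) & set(
            t1[t1["split"] != "train"]["patient_id"]
        )

    @pytest.mark.parametrize("trial", range(100))
    def test_greedy_equals_bruteforce_maximum_matching(self, trial):
        """Seeded greedy exact matching attains the maximum matching size."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 21))
        rows = []
        for i in range(n):
            rows.append(
                (
                    f"p{i}",
                    "case" if rng.random() < 0.4 else "control",
                    int(rng.integers(60, 63)),
                    "female" if rng.random() < 0.5 else "male",
                    int(rng.integers(1, 3)),
                )
            )
        table = self._table(rows)
        cases = [
            (r.age_at_start, r.sex, r.imd)
            for r in table.itertuples()
            if r.label == "case"
        ]
        controls = [
            (r.age_at_start, r.sex, r.imd)
            for r in table.itertuples()
            if r.label == "control"
        ]
        expected = brute_force_max_matching(cases, controls)
        cfg = CohortConfig(test_fraction=0.01, calib_fraction=0.0, seed=trial)
        if expected == 0:
            with pytest.raises(ValueError, match="no matched training set"):
                split_and_match(table, cfg)
            return
        # disable the test split for an exact head count
        cfg = CohortConfig(test_fraction=1e-9, calib_fraction=0.0, seed=trial)
        out = split_and_match(table, cfg)
        train = out[out["split"] == "train"]
        assert (train["label"] == "case").sum() == expected


class TestFolds:
    def _matched(self, n_pairs):
        rows = []
        for i in range(n_pairs):
            rows.append((f"c{i}", "case", f"k{i}"))
            rows.append((f"k{i}", "control", f"c{i}"))
        df = pd.DataFrame(rows, columns=["patient_id", "label", "matched_to"])
        df["split"] = "train"
        return df

    def test_divisible_case(self):
        out = make_folds(self._matched(10), 5, seed=0)
        sizes = out.groupby("fold").size()
        assert (sizes == 4).all()  # 2 pairs -> 4 patients per fold

    def test_balanced_partition_with_remainder(self):
        out = make_folds(self._matched(11), 5, seed=0)
        pair_sizes = sorted(
            out[out["label"] == "case"].groupby("fold").size(), reverse=True
        )
        assert pair_sizes == [3, 2, 2, 2, 2]

    def test_partition_properties_and_pair_coassignment(self):
        out = make_folds(self._matched(13), 4, seed=3)
        assert out["fold"].notna().all()
        by_id = out.set_index("patient_id")["fold"]
        for r in out.itertuples():
            assert by_id[r.matched_to] == r.fold
        assert set(out["fold"].unique()) == {1, 2, 3, 4}

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(self._matched(3), 5, seed=0)
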
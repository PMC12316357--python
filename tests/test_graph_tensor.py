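"""Vocabulary ranking, tensor construction vs naive oracle, coverage."""

import numpy as np
import pandas as pd
import pytest

from tgehr.graph_tensor import (
    GraphConfig,
    UnrepresentablePatient,
    Vocabulary,
    build_tensor,
    build_vocabulary,
    count_predictors,
    ehr_coverage,
    to_dense,
)
from tgehr.synthetic_ehr import PRESCRIPTION_TOKENS

from conftest import tensor_bruteforce


def _events(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "code", "source"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def _clinical(pid, date, code):
    return (pid, date, code, "clinical")


class TestVocabulary:
    def test_single_dominant_token_coverage(self):
        rows = [_clinical("A", "2001-01-01", "X")] * 99 + [
            _clinical("A", "2001-01-02", "Y")
        ]
        vocab = build_vocabulary(_events(rows), V=1)
        assert vocab.clinical_nodes == ("X",)
        assert vocab.coverage_fraction == pytest.approx(0.99)

    def test_full_vocabulary_saturates(self):
        rows = [
            _clinical("A", "2001-01-01", "X"),
            _clinical("A", "2001-01-02", "Y"),
            _clinical("B", "2001-01-03", "Z"),
        ]
        vocab = build_vocabulary(_events(rows), V=3)
        assert vocab.coverage_fraction == 1.0

    def test_ten_token_corpus_hand_tally(self):
        # counts: a=5, b=4, c=3, d=2, e..j=1 each -> total 20
        rows = []
        for tok, n in [("a", 5), ("b", 4), ("c", 3), ("d", 2)] + [
            (t, 1) for t in "efghij"
        ]:
            rows += [_clinical("A", "2001-01-01", tok)] * n
        vocab = build_vocabulary(_events(rows), V=3)
        assert vocab.clinical_nodes == ("a", "b", "c")
        assert vocab.coverage_fraction == pytest.approx(12 / 20)

    def test_frequency_ties_broken_lexicographically(self):
        rows = [_clinical("A", "2001-01-01", t) for t in ("zz", "aa", "mm")]
        vocab = build_vocabulary(_events(rows), V=2)
        assert vocab.clinical_nodes == ("aa", "mm")

    def test_prescription_nodes_always_last_six(self):
        rows = [_clinical("A", "2001-01-01", "X")]
        vocab = build_vocabulary(_events(rows), V=1)
        idx = vocab.index_of
        assert [idx[t] for t in PRESCRIPTION_TOKENS] == [1, 2, 3, 4, 5, 6]

    def test_oversized_v_clamped_with_warning(self):
        rows = [_clinical("A", "2001-01-01", "X")]
        with pytest.warns(UserWarning, match="clamping"):
            vocab = build_vocabulary(_events(rows), V=99)
        assert vocab.clinical_nodes == ("X",)

    @pytest.mark.parametrize(
        "V,n_demo,expected", [(512, 3, 521), (1, 0, 7), (32, 3, 41)]
    )
    def test_predictor_count(self, V, n_demo, expected):
        vocab = Vocabulary(
            clinical_nodes=tuple(f"t{i}" for i in range(V)), coverage_fraction=1.0
        )
        assert count_predictors(vocab, n_demo) == expected


class TestTensor:
    CFG = GraphConfig(V=4, k_max=5)

    def _vocab(self, tokens=("a", "b", "c", "d")):
        return Vocabulary(clinical_nodes=tuple(tokens), coverage_fraction=1.0)

    def test_single_transition_months(self):
        ev = _events(
            [_clinical("A", "2001-01-01", "a"), _clinical("A", "2001-04-02", "b")]
        )
        t = build_tensor(ev, self._vocab(), self.CFG)
        dense = to_dense(t)
        nz = np.argwhere(dense > 0)
        assert len(nz) == 1
        k, i, j = nz[0]
        assert (i, j) == (0, 1)
        assert k == self.CFG.k_max - 2  # front padding: last slice holds recency
        assert dense[k, i, j] == pytest.approx(91 / 30.44, abs=1e-3)

    def test_cross_product_edges_all_equal(self):
        ev = _events(
            [
                _clinical("A", "2001-01-01", "a"),
                _clinical("A", "2001-01-01", "b"),
                _clinical("A", "2001-02-01", "b"),
                _clinical("A", "2001-02-01", "c"),
                _clinical("A", "2001-02-01", "d"),
            ]
        )
        t = build_tensor(ev, self._vocab(), self.CFG)
        dense = to_dense(t)
        nz = dense[dense > 0]
        assert len(nz) == 6  # 2 source codes x 3 target codes
        assert np.allclose(nz, nz[0])

    def test_five_visit_patient_truncated_to_k_max(self):
        cfg = GraphConfig(V=4, k_max=3)
        dates = ["2001-01-01", "2001-02-01", "2001-03-01", "2001-04-01", "2001-05-01"]
        ev = _events([_clinical("A", d, "a") for d in dates])
        t = build_tensor(ev, self._vocab(), cfg)
        dense = to_dense(t)
        # only the last 2 transitions (Mar->Apr, Apr->May) survive
        assert t.n_visits_used == 3
        assert dense.shape[0] == 2
        assert np.count_nonzero(dense) == 2
        assert dense[0, 0, 0] == pytest.approx(31 / 30.44, abs=1e-3)
        assert dense[1, 0, 0] == pytest.approx(30 / 30.44, abs=1e-3)

    def test_out_of_vocabulary_codes_dropped_and_counted(self):
        ev = _events(
            [
                _clinical("A", "2001-01-01", "a"),
                _clinical("A", "2001-01-01", "UNKNOWN"),
                _clinical("A", "2001-02-01", "b"),
            ]
        )
        t = build_tensor(ev, self._vocab(), self.CFG)
        assert t.n_oov_dropped == 1
        assert np.count_nonzero(to_dense(t)) == 1

    def test_under_two_visits_unrepresentable(self):
        ev = _events([_clinical("A", "2001-01-01", "a")])
        with pytest.raises(UnrepresentablePatient):
            build_tensor(ev, self._vocab(), self.CFG)

    @pytest.mark.parametrize("trial", range(200))
    def test_matches_naive_triple_loop_oracle(self, trial):
        """Sparse builder equals dense brute-force construction exactly."""
        rng = np.random.default_rng(trial)
        n_tokens = int(rng.integers(2, 9))
        tokens = [f"t{i}" for i in range(n_tokens)]
        vocab = Vocabulary(clinical_nodes=tuple(tokens), coverage_fraction=1.0)
        k_max = int(rng.integers(2, 8))
        n_visits = int(rng.integers(2, 11))
        days = np.sort(
            rng.choice(np.arange(0, 400), size=n_visits, replace=False)
        )
        rows, codes_by_date = [], {}
        for d in days:
            date = pd.Timestamp("2001-01-01") + pd.Timedelta(days=int(d))
            n_pick = int(rng.integers(1, min(4, n_tokens + 1)))
            picked = rng.choice(n_tokens, size=n_pick, replace=False)
            codes_by_date[date] = sorted(int(p) for p in picked)
            rows += [_clinical("A", date, tokens[p]) for p in picked]
        cfg = GraphConfig(V=n_tokens, k_max=k_max)
        t = build_tensor(_events(rows), vocab, cfg)
        oracle = tensor_bruteforce(
            list(codes_by_date), codes_by_date, vocab.n_nodes, k_max, 30.44
        )
        np.testing.assert_array_equal(to_dense(t), oracle)

    def test_permutation_equivariance(self):
        """Relabeling vocabulary indices permutes tensor axes and nothing else."""
        rng = np.random.default_rng(0)
        tokens = ["a", "b", "c", "d"]
        rows = []
        for d in ("2001-01-01", "2001-02-01", "2001-03-15"):
            for tok in rng.choice(tokens, size=2, replace=False):
                rows.append(_clinical("A", d, tok))
        ev = _events(rows)
        vocab1 = Vocabulary(clinical_nodes=tuple(tokens), coverage_fraction=1.0)
        perm = [2, 0, 3, 1]
        vocab2 = Vocabulary(
            clinical_nodes=tuple(tokens[p] for p in perm), coverage_fraction=1.0
        )
        d1 = to_dense(build_tensor(ev, vocab1, self.CFG))
        d2 = to_dense(build_tensor(ev, vocab2, self.CFG))
        # node index of token t under vocab2: position of t in permuted list
        mapping = {tokens[p]: i for i, p in enumerate(perm)}
        pi = np.array(
            [mapping[t] for t in tokens]
            + list(range(len(tokens), vocab1.n_nodes))
        )
        np.testing.assert_array_equal(d1, d2[np.ix_(range(d2.shape[0]), pi, pi)])

    def test_truncation_ignores_ancient_events(self):
        """Events older than the k_max-th most recent visit never matter."""
        cfg = GraphConfig(V=4, k_max=3)
        recent = [
            _clinical("A", "2002-01-01", "a"),
            _clinical("A", "2002-02-01", "b"),
            _clinical("A", "2002-03-01", "c"),
        ]
        ancient = [_clinical("A", "1999-05-05", "d"), _clinical("A", "1999-06-06", "d")]
        t1 = build_tensor(_events(recent), self._vocab(), cfg)
        t2 = build_tensor(_events(ancient + recent), self._vocab(), cfg)
        np.testing.assert_array_equal(to_dense(t1), to_dense(t2))


class TestCoverage:
    def _patient(self, month_offsets):
        rows = [
            _clinical("A", pd.Timestamp("2001-01-01") + pd.DateOffset(months=m), "a")
            for m in month_offsets
        ]
        return _events(rows)

    def test_few_visits_fully_covered(self):
        assert ehr_coverage(self._patient(range(50)), k_max=200) == 1.0

    def test_single_visit_by_convention(self):
        assert ehr_coverage(self._patient([0]), k_max=3) == 1.0

    def test_timespan_arithmetic(self):
        ev = self._patient([0, 12, 24, 36])
        # last 3 visits span months 12..36 out of 0..36
        assert ehr_coverage(ev, k_max=3) == pytest.approx(2 / 3, abs=1e-3)

    def test_monotone_in_k_max(self, small_cohort):
        _, events, _ = small_cohort
        fracs = []
        for k in (200, 150, 100, 5):
            cov = [
                ehr_coverage(g, k) for _, g in events.groupby("patient_id")
            ]
            fracs.append(np.mean([c == 1.0 for c in cov]))
        assert fracs == sorted(fracs, reverse=True)
        for _, g in list(events.groupby("patient_id"))[:20]:
            per_patient = [ehr_coverage(g, k) for k in (5, 10, 50)]
            assert per_patient == sorted(per_patient)
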
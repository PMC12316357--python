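"""Comparison models on atemporal representations of the same histories.

The count-based baselines (logistic regression, random forest) see code
counts over the vocabulary nodes plus encoded demographics; the RNN baseline
sees the order-preserved code-index sequence of the last k_max visits with
no inter-visit times and no demographics. None of them receives temporal
gap information, so any discrimination gap versus the temporal-graph model
on data whose signal lives in the gaps is attributable to the edge times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .graph_tensor import Vocabulary
from .tgcnn import DemographicsEncoder, _Adam

__all__ = ["vectorize", "code_sequences", "fit_baseline", "BaselineScorer", "RnnBaseline"]


def vectorize(
    patient_events: pd.DataFrame,
    vocabulary: Vocabulary,
    demographics: pd.Series | dict,
    encoder: DemographicsEncoder,
) -> np.ndarray:
    """Pure code-count feature vector (no temporal information) + demographics."""
    index = vocabulary.index_of
    counts = np.zeros(vocabulary.n_nodes)
    for code in patient_events["code"]:
        i = index.get(code)
        if i is not None:
            counts[i] += 1
    demo = encoder.transform(pd.DataFrame([dict(demographics)]))[0]
    return np.concatenate([counts, demo])


def code_sequences(
    events_by_patient: dict[str, pd.DataFrame],
    patient_ids,
    vocabulary: Vocabulary,
    k_max: int,
    max_len: int = 64,
) -> list[np.ndarray]:
    """Order-preserved code-index sequences (last k_max visits, no gap times)."""
    index = vocabulary.index_of
    out = []
    for pid in patient_ids:
        ev = events_by_patient.get(pid)
        seq: list[int] = []
        if ev is not None and len(ev):
            ev = ev[ev["code"].isin(index)]
            by_date: dict[pd.Timestamp, list[int]] = {}
            for d, code in zip(ev["date"], ev["code"]):
                by_date.setdefault(pd.Timestamp(d), []).append(index[code])
            for d in sorted(by_date)[-k_max:]:
                seq.extend(sorted(by_date[d]))
        out.append(np.asarray(seq[-max_len:], dtype=int))
    return out


@dataclass
class BaselineScorer:
    kind: str
    model: object

    def predict_proba(self, X) -> np.ndarray:
        if self.kind == "rnn":
            return self.model.predict_proba(X)
        return self.model.predict_proba(np.asarray(X))[:, 1]


class RnnBaseline:
    """Single-layer tanh recurrence over learned code embeddings (NumPy).

    Sequences are left-padded (hidden state pinned to zero until the
    sequence starts) so every history ends at the final step; gradients are
    hand-derived and Adam-optimised, all randomness seeded.
    """

    def __init__(self, n_nodes, embed_dim=8, hidden=16, lr=0.02, epochs=12,
                 batch_size=64, seed=0):
        self.n_nodes = n_nodes
        self.embed_dim = embed_dim
        self.hidden = hidden
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None

    def _pad(self, seqs) -> tuple[np.ndarray, np.ndarray]:
        T = max((len(s) for s in seqs), default=1) or 1
        X = np.zeros((len(seqs), T), dtype=int)
        active = np.zeros((len(seqs), T), dtype=bool)
        for b, s in enumerate(seqs):
            if len(s):
                X[b, T - len(s):] = s
                active[b, T - len(s):] = True
        return X, active

    def _forward(self, X, active, p):
        B, T = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        hs, caches = [h], []
        for t in range(T):
            e = p["Emb"][X[:, t]]
            a = e @ p["Wx"].T + h @ p["Wh"].T + p["bh"]
            h_new = np.tanh(a)
            h = np.where(active[:, t : t + 1], h_new, 0.0)
            hs.append(h)
            caches.append((e, h_new))
        logit = h @ p["wo"] + p["bo"]
        prob = 1.0 / (1.0 + np.exp(-logit))
        return prob, hs, caches

    def _loss_and_grads(self, X, active, y, p):
        prob, hs, caches = self._forward(X, active, p)
        B, T = X.shape
        eps = 1e-12
        loss = -float(np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = (prob - y) / B
        g["wo"] = hs[-1].T @ dlogit
        g["bo"] = np.array(dlogit.sum())
        dh = np.outer(dlogit, p["wo"])
        for t in range(T - 1, -1, -1):
            e, h_new = caches[t]
            act = active[:, t : t + 1]
            da = dh * act * (1.0 - h_new**2)
            g["Wx"] += da.T @ e
            g["Wh"] += da.T @ hs[t]
            g["bh"] += da.sum(axis=0)
            de = da @ p["Wx"]
            np.add.at(g["Emb"], X[:, t], de)
            # inactive steps pin h to zero, cutting the backward path there
            dh = da @ p["Wh"]
        return loss, g

    def fit(self, seqs, y):
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        E, H = self.embed_dim, self.hidden
        p = {
            "Emb": rng.normal(0, 0.1, size=(self.n_nodes, E)),
            "Wx": rng.normal(0, 1 / np.sqrt(E), size=(H, E)),
            "Wh": rng.normal(0, 1 / np.sqrt(H), size=(H, H)),
            "bh": np.zeros(H),
            "wo": rng.normal(0, 1 / np.sqrt(H), size=H),
            "bo": np.array(0.0),
        }
        opt = _Adam(p, self.lr)
        n = len(seqs)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                b = order[s : s + self.batch_size]
                X, active = self._pad([seqs[i] for i in b])
                loss, grads = self._loss_and_grads(X, active, y[b], p)
                if not np.isfinite(loss):
                    raise RuntimeError("non-finite RNN baseline loss")
                opt.step(p, grads)
        self.params = p
        return self

    def predict_proba(self, seqs) -> np.ndarray:
        X, active = self._pad(seqs)
        prob, _, _ = self._forward(X, active, self.params)
        return prob


def fit_baseline(kind: str, train_input, labels, seed: int = 0,
                 n_nodes: int | None = None) -> BaselineScorer:
    """Fit one comparison model; returns a deterministic probability scorer.

    ``train_input`` is a feature matrix for logistic/random_forest and a list
    of code-index sequences for the rnn (``n_nodes`` required there).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("baseline training requires both outcome classes")
    if kind == "logistic":
        model = LogisticRegression(max_iter=2000, random_state=seed)
        model.fit(np.asarray(train_input), y)
    elif kind == "random_forest":
        model = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        model.fit(np.asarray(train_input), y)
    elif kind == "rnn":
        if n_nodes is None:
            raise ValueError("rnn baseline needs n_nodes")
        model = RnnBaseline(n_nodes=n_nodes, seed=seed).fit(train_input, y.astype(float))
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return BaselineScorer(kind=kind, model=model)
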
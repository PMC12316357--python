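"""Controlled experiments: null pipeline, signal recovery, temporal advantage.

Three experiments on the full pipeline, each answering one question:

* null      - with the planted signal off, does the end-to-end pipeline
              stay at chance discrimination? (leakage guard)
* recovery  - does test AUROC rise monotonically with the planted signal
              strength, and is a strong signal recovered?
* temporal  - when classes differ only in inter-visit gap dynamics
              (identical code mix and counts), do count-based baselines
              stay at chance while the temporal-graph model discriminates?

Writes results/experiments.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tgehr.cohort import CohortConfig
from tgehr.graph_tensor import GraphConfig
from tgehr.pipeline import run_pipeline
from tgehr.synthetic_ehr import SimConfig
from tgehr.tgcnn import ModelConfig

GRAPH = GraphConfig(V=32, k_max=20)


def _run(seed, signal, **kw):
    models = kw.pop("models", ("tgcnn",))
    sim_kw = {k: kw.pop(k) for k in ("temporal_signal_only",) if k in kw}
    res = run_pipeline(
        SimConfig(n_patients=1000, signal_strength=signal, seed=seed, **sim_kw),
        CohortConfig(horizon_years=1, seed=seed, **kw),
        GRAPH,
        ModelConfig(seed=seed),
        models=models,
    )
    return res.test_auroc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    rows = []

    nulls = [_run(seed, 0.0, test_fraction=0.30)["tgcnn"] for seed in (1, 2, 3)]
    print(f"null pipeline AUROC: {[round(a, 3) for a in nulls]} "
          f"(mean {np.mean(nulls):.3f}; chance is 0.5)")
    rows += [{"experiment": "null", "seed": s, "model": "tgcnn", "auroc": a}
             for s, a in zip((1, 2, 3), nulls)]

    for strength in (0.0, 1.0, 2.0):
        vals = [_run(seed, strength)["tgcnn"] for seed in (3, 4, 5)]
        print(f"signal {strength}: AUROC {[round(v, 3) for v in vals]} "
              f"(mean {np.mean(vals):.3f})")
        rows += [{"experiment": f"recovery_s{strength}", "seed": s,
                  "model": "tgcnn", "auroc": a} for s, a in zip((3, 4, 5), vals)]

    temporal = _run(11, 2.0, temporal_signal_only=True, test_fraction=0.2,
                    models=("tgcnn", "logistic", "random_forest"))
    print("temporal-only signal:",
          {k: round(v, 3) for k, v in temporal.items()},
          "(count models should sit near 0.5)")
    rows += [{"experiment": "temporal_only", "seed": 11, "model": m, "auroc": a}
             for m, a in temporal.items()]

    args.dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.dir / "experiments.csv", index=False)
    print(f"wrote {args.dir}/experiments.csv")


if __name__ == "__main__":
    main()
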
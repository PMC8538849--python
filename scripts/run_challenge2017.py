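#!/usr/bin/env python
"""Optional: rerun the full protocol on the real Challenge database.

This script is documentation of the full-scale procedure; it is never
exercised by the test suite.  It expects a local copy of the PhysioNet
Computing in Cardiology Challenge 2017 training set (8528 single-lead
records with the v3 reference labels), converted to 2-column
(time_s, mv) CSV files:

    python scripts/run_challenge2017.py --records <dir> \
        --labels REFERENCE-v3.csv --out results/

Pipeline: extract the 137 features from every record, run 5 x 5-fold
stratified cross-validation of the 128-32-4 topology with the published
optimal class weights (0.23, 0.25, 0.3, 0.22), batch 128, learning rate
0.001, then aggregate global weights importance over all trained models
and report the class-cumulative feature ranking.  Expect hours of
runtime on a workstation.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from densecg.evaluate import run_cv
from densecg.features import default_registry, extract_table
from densecg.importance import global_weights_importance, rank_by_cum_gwi
from densecg.io import read_ecg, read_feature_table, write_feature_table
from densecg.net import Topology, TrainingConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--records", type=Path, required=True,
                    help="directory of per-record (time_s, mv) CSV files")
    ap.add_argument("--labels", type=Path, required=True,
                    help="CSV with columns record,label (N/AF/O/X)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--runs", type=int, default=5)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    reg = default_registry()
    feat_csv = args.out / "features.csv"
    if not feat_csv.exists():
        ref = pd.read_csv(args.labels, header=None,
                          names=["record", "label"])
        records, labels = [], []
        for _, row in ref.iterrows():
            records.append(read_ecg(args.records / f"{row.record}.csv"))
            labels.append(row.label)
        df = extract_table(records, reg, labels=labels)
        write_feature_table(feat_csv, df[reg.names].to_numpy(),
                            df["label"], reg)
    X, y, _ = read_feature_table(feat_csv, reg)

    topo = Topology(len(reg), (128, 32))
    cfg = TrainingConfig(class_weights=(0.23, 0.25, 0.3, 0.22),
                         batch_size=128, learning_rate=0.001,
                         seed=args.seed)
    res = run_cv(X, y, topo, cfg, k=5, n_runs=args.runs)
    rep = res.mean_report
    (args.out / "cv_metrics.json").write_text(json.dumps({
        "f1": rep.f1, "f1_total": rep.f1_total,
        "acc_total_pct": rep.acc_total_pct,
        "per_run_f1": res.per_run_f1}, indent=2))

    gwis = [global_weights_importance(m, X) for m in res.models]
    ranking = rank_by_cum_gwi(gwis)
    pd.DataFrame({"feature": [reg.names[i] for i in ranking.indices],
                  "cumGWI": ranking.scores}).to_csv(
        args.out / "feature_ranking.csv", index=False)
    print(f"F1(Total) = {rep.f1_total:.3f}; outputs in {args.out}/")


if __name__ == "__main__":
    main()
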
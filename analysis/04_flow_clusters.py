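#!/usr/bin/env python
"""Cluster neck-connective types by sensorimotor flow profile (UMAP +
silhouette-swept k-means), score clusters against the rule-based behaviour
compatibility matrices, and evaluate recovery of planted behaviours.

Requires 03_sensorimotor_flow.py to have been run with the same seed.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from dimflow.clustering import (behaviour_compatibility_matrices,
                                evaluate_multilabel_auc)
from dimflow.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    manifest = run_pipeline(["cluster"], {}, OUT, seed=args.seed)
    info = manifest["stages"]["cluster"]
    print(f"k = {info['k']} clusters (silhouette {info['silhouette']:.3f})")
    clusters = pd.read_csv(OUT / "clusters.csv")
    scores = pd.read_csv(OUT / "compatibility_scores.csv", index_col=0)
    truth = json.loads((OUT / "sensorimotor_truth.json").read_text())
    mats = behaviour_compatibility_matrices()
    lab = dict(zip(clusters["type"], clusters["cluster"]))
    ann = {}
    for cid in scores.index:
        routes = {tuple(truth["route_membership"][n]) for n in lab
                  if lab[n] == cid and n in truth["route_membership"]}
        ann[cid] = {m.behaviour for m in mats
                    for (mo, do) in routes if m.entries.loc[mo, do]}
    auc = evaluate_multilabel_auc(scores, ann)
    print(f"multilabel behaviour-compatibility ROC AUC vs planted routes: "
          f"{auc:.3f}")
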
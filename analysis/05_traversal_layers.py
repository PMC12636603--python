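#!/usr/bin/env python
"""Probabilistic graph traversal from all sensory neurons: mean layer per
neuron over repeated stochastic traversals, compared with the generator's
feedforward layer index.

Requires 01_simulate_connectomes.py to have been run with the same seed.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from dimflow.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    run_pipeline(["traverse"], {}, OUT, seed=args.seed)
    layers = pd.read_csv(OUT / "traversal_layers.csv").set_index("type")
    truth = json.loads((OUT / "sensorimotor_truth.json").read_text())
    reached = layers["mean_layer"].dropna()
    print(f"{len(reached)} of {len(layers)} neurons reached; mean layer "
          f"range {reached.min():.2f}-{reached.max():.2f}")
    members = [n for n in truth["route_membership"] if n in reached.index]
    rho = spearmanr([truth["layer_index"][n] for n in members],
                    [reached[n] for n in members]).statistic
    print(f"Spearman rho between traversal layer and generator layer on "
          f"planted routes: {rho:.3f}")
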
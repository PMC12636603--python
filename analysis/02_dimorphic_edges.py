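#!/usr/bin/env python
"""Run the paired male/female edge comparison on the simulated connectomes:
scale estimation, noise thresholds, per-edge t statistics with BH FDR, the
30% effect-size filter, type-label reconciliation and summary fractions.

Requires 01_simulate_connectomes.py to have been run with the same seed.
"""

import argparse
import json
from pathlib import Path

from dimflow.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    run_pipeline(["dimorphism"], {}, OUT, seed=args.seed)
    summ = json.loads((OUT / "dimorphism_summary.json").read_text())
    truth = json.loads((OUT / "truth.json").read_text())
    print(f"estimated scale factor: {summ['scale_factor']:.4f} "
          f"(generator: {truth['true_scale']:.4f})")
    print(f"{summ['n_noisy']} noisy edges excluded; {summ['n_tested']} tested")
    print(f"dimorphic edge fraction: male {summ['frac_dimorphic_edges_male']:.3f}, "
          f"female {summ['frac_dimorphic_edges_female']:.3f}")
    print(f"dimorphic synapse fraction: male "
          f"{summ['frac_dimorphic_synapses_male']:.3f}, "
          f"female {summ['frac_dimorphic_synapses_female']:.3f}")
    print(f"{len(summ['secondarily_dimorphic_types'])} secondarily dimorphic "
          f"types (isomorphic morphology, dimorphic connectivity)")
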
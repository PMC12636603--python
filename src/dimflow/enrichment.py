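"""Hypergeometric cluster enrichment and within-community synapse fractions.

Given nested partitions of cell types (e.g. from hierarchical community
detection) and a binary categorization (isomorphic vs non-isomorphic, the
latter covering dimorphic and sex-specific types), each cluster is scored
by the exact hypergeometric tail probability of containing at least its
observed number of non-isomorphic types, with one Benjamini–Hochberg
correction applied jointly across all clusters of all levels.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .dimorphism import fdr_adjust
from .graph import ConnectomeGraph

__all__ = ["hypergeometric_enrichment", "within_community_fraction"]


def hypergeometric_enrichment(assignments: list[dict], categories: dict,
                              alpha: float = 0.01) -> pd.DataFrame:
    """Exact enrichment test for non-isomorphic types per cluster.

    Parameters
    ----------
    assignments:
        One ``{type: cluster_id}`` map per hierarchy level.
    categories:
        ``{type: "isomorphic" | anything-else}``; non-"isomorphic" counts
        as non-isomorphic.
    alpha:
        FDR level; a cluster is enriched iff its BH-adjusted q ≤ alpha.

    Returns a DataFrame with one row per (level, cluster): n_total,
    n_noniso, p (exact tail P(X ≥ k)), q and the enriched flag.
    """
    rows = []
    for level, assign in enumerate(assignments):
        missing = [t for t in assign if t not in categories]
        if missing:
            raise ValueError(f"uncategorized types at level {level}: {missing[:5]}")
        N = len(assign)
        K = sum(1 for t in assign if categories[t] != "isomorphic")
        per: dict = {}
        for t, c in assign.items():
            tot, non = per.get(c, (0, 0))
            per[c] = (tot + 1, non + (categories[t] != "isomorphic"))
        for c, (n, k) in sorted(per.items()):
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
            rows.append({"level": level, "cluster": c, "n_total": n,
                         "n_noniso": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["q"] = fdr_adjust(df["p"].to_numpy())
    df["enriched"] = df["q"] <= alpha
    return df


def within_community_fraction(graph: ConnectomeGraph,
                              assignments: list[dict]) -> dict:
    """Fraction of each cluster's synapses that stay inside the cluster.

    For every cluster the fraction is (synapses with both endpoints in the
    cluster) / (synapses with at least one endpoint in the cluster); each
    boundary synapse counts once per incident cluster.  The per-level
    entry ``"__mean__"`` is the synapse-weighted mean over clusters.
    """
    out = {}
    for level, assign in enumerate(assignments):
        missing = [t for t in
                   set(graph.edges["pre"]) | set(graph.edges["post"])
                   if t not in assign]
        if missing:
            raise ValueError(f"unassigned endpoints at level {level}: {missing[:5]}")
        internal: dict = {}
        touching: dict = {}
        for pre, post, w in zip(graph.edges["pre"], graph.edges["post"],
                                graph.edges["weight_total"]):
            a, b = assign[pre], assign[post]
            touching[a] = touching.get(a, 0.0) + w
            if a == b:
                internal[a] = internal.get(a, 0.0) + w
            else:
                touching[b] = touching.get(b, 0.0) + w
        fracs = {c: internal.get(c, 0.0) / tot for c, tot in touching.items()}
        tot_all = sum(touching.values())
        fracs["__mean__"] = (
            sum(fracs[c] * touching[c] for c in touching) / tot_all
            if tot_all else 0.0)
        out[level] = fracs
    return out
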
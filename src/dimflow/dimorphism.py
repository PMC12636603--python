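"""Paired male/female edge-comparison pipeline.

The comparison works on a *paired edge table*: one row per type-to-type
connection with left/right/total synapse counts in each sex.  The stages
are

1. cross-dataset **scale factor** estimation (males have systematically more
   synapses) and rescaling of the male weights;
2. **noise thresholds** below which an edge's presence is unreliable;
3. a per-edge **t statistic** using the two hemispheres of each sex as
   within-animal replicates, with p-values from a t distribution with 3
   degrees of freedom and Benjamini–Hochberg FDR control;
4. an **effect-size filter** (≥30% relative difference) and categorical
   calls (noisy / isomorphic / dimorphic);
5. **reconciliation** with type-level dimorphism labels;
6. summary fractions of dimorphic edges/synapses per sex and
   *secondarily dimorphic* types (morphologically isomorphic types with
   dimorphic connectivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph import ConnectomeGraph

__all__ = [
    "DEFAULT_NOISE_THRESHOLDS",
    "build_paired_table",
    "estimate_scale_factor",
    "estimate_noise_threshold",
    "hemisphere_t_statistic",
    "edge_p_values",
    "fdr_adjust",
    "classify_edges",
    "reconcile_with_type_labels",
    "dimorphism_summary",
    "DimorphismSummary",
]

#: Reliability thresholds on raw synapse counts (male, female).  An edge
#: below both is treated as noise and excluded from testing.  These follow
#: the persistence-derived constants for paired fly-brain datasets (>10
#: male, >7 female synapses for a 90% chance of cross-dataset persistence);
#: the denser (male) dataset gets the higher threshold.  Persistence-based
#: estimation is available via :func:`estimate_noise_threshold`.
DEFAULT_NOISE_THRESHOLDS = (11, 8)


class EstimationError(RuntimeError):
    """Raised when a scale factor or noise threshold cannot be estimated."""


def build_paired_table(male: ConnectomeGraph, female: ConnectomeGraph
                       ) -> pd.DataFrame:
    """Outer-join the two edge tables on (pre, post).

    Edges absent from one dataset get zero weights there.  Only edges whose
    endpoints are cross-matched types (present in both datasets) are
    *matched*; edges touching a sex-specific type are retained and flagged
    ``matched=False``.
    """
    cols = ["pre", "post", "weight_left", "weight_right", "weight_total"]
    m = male.edges[cols].rename(columns={
        "weight_left": "male_left", "weight_right": "male_right",
        "weight_total": "male_total"})
    f = female.edges[cols].rename(columns={
        "weight_left": "female_left", "weight_right": "female_right",
        "weight_total": "female_total"})
    paired = m.merge(f, on=["pre", "post"], how="outer").fillna(0.0)
    if male.types is not None and female.types is not None:
        both = set(male.types["type"]) & set(female.types["type"])
        paired["matched"] = paired["pre"].isin(both) & paired["post"].isin(both)
    else:
        paired["matched"] = True
    return paired.sort_values(["pre", "post"]).reset_index(drop=True)


def estimate_scale_factor(paired: pd.DataFrame,
                          thresholds: tuple[float, float] = DEFAULT_NOISE_THRESHOLDS,
                          space: str = "log") -> float:
    """Estimate the factor s that maps male totals onto the female scale.

    Restricted to matched edges above the noise threshold in both sexes.
    ``space="log"`` (default) fits the unit-slope principal axis of the
    log-weight cloud, i.e. the geometric-mean female/male ratio, which is
    robust to the heavy weight tail.  ``space="raw"`` takes the component
    ratio (female loading / male loading) of the first principal axis of
    the centered raw-weight cloud.
    """
    sel = paired[(paired["male_total"] >= thresholds[0])
                 & (paired["female_total"] >= thresholds[1])
                 & paired.get("matched", True)]
    if len(sel) < 10:
        raise EstimationError(
            f"only {len(sel)} usable rows above thresholds {thresholds}")
    m = sel["male_total"].to_numpy(float)
    f = sel["female_total"].to_numpy(float)
    if space == "log":
        return float(np.exp(np.mean(np.log(f)) - np.mean(np.log(m))))
    if space == "raw":
        X = np.column_stack([m, f])
        X = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        v = vt[0]
        if v[0] == 0:
            raise EstimationError("degenerate principal axis")
        return float(abs(v[1] / v[0]))
    raise ValueError(f"unknown space {space!r}")


def estimate_noise_threshold(paired: pd.DataFrame, direction: str,
                             persistence: float = 0.9) -> int:
    """Smallest integer weight at which cross-dataset persistence is reached.

    For ``direction="male"``: the smallest w such that, among edges with
    male total ≥ w, the fraction also present in the female dataset
    (total > 0) is at least ``persistence``.
    """
    if direction not in ("male", "female"):
        raise ValueError(f"direction must be 'male' or 'female', got {direction!r}")
    src = paired[f"{direction}_total"].to_numpy(float)
    oth = paired[("female" if direction == "male" else "male") + "_total"].to_numpy(float)
    mask = paired.get("matched", pd.Series(True, index=paired.index)).to_numpy(bool)
    src, oth = src[mask & (src > 0)], oth[mask & (src > 0)]
    if src.size == 0:
        raise EstimationError("no edges present in the source dataset")
    best = 0.0
    for w in range(1, int(np.max(src)) + 1):
        sel = src >= w
        if sel.sum() < 10:
            break
        frac = float((oth[sel] > 0).mean())
        best = max(best, frac)
        if frac >= persistence:
            return w
    raise EstimationError(
        f"persistence {persistence} unreachable; attained maximum {best:.3f}")


def hemisphere_t_statistic(male_left, male_right, female_left, female_right):
    """Two-hemisphere t statistic for one edge (vectorized).

    t = (x̄m − x̄f) / s_p with x̄ the mean of the two hemisphere weights,
    per-sex SD s = |left − right|/√2 (sample SD for n = 2) and pooled SD
    s_p = √((s_m² + s_f²)/2).  Zero pooled SD gives ±∞ when the means
    differ and 0 when they are equal.
    """
    ml, mr = np.asarray(male_left, float), np.asarray(male_right, float)
    fl, fr = np.asarray(female_left, float), np.asarray(female_right, float)
    xm, xf = (ml + mr) / 2.0, (fl + fr) / 2.0
    s2m = (ml - mr) ** 2 / 2.0
    s2f = (fl - fr) ** 2 / 2.0
    sp = np.sqrt((s2m + s2f) / 2.0)
    diff = xm - xf
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sp > 0, diff / np.where(sp > 0, sp, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return t if t.ndim else float(t)


def edge_p_values(t, df: int = 3):
    """Two-sided p-values from the t distribution with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = np.asarray(t, float)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df=df))
    return p if p.ndim else float(p)


def fdr_adjust(p):
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def classify_edges(paired: pd.DataFrame, q_threshold: float = 0.1,
                   min_rel_diff: float = 0.3,
                   thresholds: tuple[float, float] = DEFAULT_NOISE_THRESHOLDS,
                   scale_factor: float | None = None,
                   df: int = 3) -> pd.DataFrame:
    """Classify every paired edge as noisy, isomorphic or dimorphic.

    Male weights are first multiplied by ``scale_factor`` (estimated from
    the table when not supplied).  Edges below the noise threshold in both
    sexes are *noisy* and excluded from testing.  The remaining edges are
    tested (t statistic, two-sided p at ``df`` degrees of freedom, BH over
    the tested set) and called dimorphic iff q ≤ ``q_threshold`` and the
    relative difference |x̄m − x̄f| / max(x̄m, x̄f) is at least
    ``min_rel_diff``.
    """
    if scale_factor is None:
        scale_factor = estimate_scale_factor(paired, thresholds)
    res = paired.copy()
    for c in ("male_left", "male_right", "male_total"):
        res[c.replace("male", "male_scaled")] = res[c] * scale_factor
    noisy = (res["male_total"] < thresholds[0]) & (res["female_total"] < thresholds[1])
    tested = ~noisy
    if not tested.any():
        raise EstimationError("no edges above the noise thresholds")

    t = hemisphere_t_statistic(res["male_scaled_left"], res["male_scaled_right"],
                               res["female_left"], res["female_right"])
    xm = (res["male_scaled_left"] + res["male_scaled_right"]) / 2.0
    xf = (res["female_left"] + res["female_right"]) / 2.0
    mx = np.maximum(xm, xf)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mx > 0, np.abs(xm - xf) / np.where(mx > 0, mx, 1.0), 0.0)

    res["t"] = t
    res["p"] = edge_p_values(t, df=df)
    res["q"] = np.nan
    res.loc[tested, "q"] = fdr_adjust(res.loc[tested, "p"].to_numpy())
    res["rel_diff"] = rel
    res["scale_factor"] = scale_factor

    category = np.where(noisy, "noisy", "isomorphic").astype(object)
    dim = tested & (res["q"] <= q_threshold) & (res["rel_diff"] >= min_rel_diff)
    category[dim.to_numpy(bool)] = "dimorphic"
    res["category"] = category
    return res


def reconcile_with_type_labels(results: pd.DataFrame,
                               annotations: pd.DataFrame) -> pd.DataFrame:
    """Correct edge categories using type-level dimorphism labels.

    Any non-noisy edge touching a sex-specific type becomes dimorphic
    (such connections cannot exist in the other sex); any edge called
    dimorphic whose endpoints are both isomorphic types is reset to
    isomorphic (presumed biological/technical variability).
    """
    label = (annotations.drop_duplicates("type").set_index("type")["dimorphism"]
             .to_dict())
    missing = (set(results["pre"]) | set(results["post"])) - set(label)
    if missing:
        raise ValueError(f"types without annotation: {sorted(missing)[:10]}")
    pre_l = results["pre"].map(label)
    post_l = results["post"].map(label)
    corrected = results["category"].copy().astype(object)
    not_noisy = results["category"] != "noisy"
    touches_ss = (pre_l == "sex_specific") | (post_l == "sex_specific")
    both_iso = (pre_l == "isomorphic") & (post_l == "isomorphic")
    corrected[not_noisy & touches_ss] = "dimorphic"
    corrected[(results["category"] == "dimorphic") & both_iso] = "isomorphic"
    out = results.copy()
    out["corrected_category"] = corrected
    return out


@dataclass
class DimorphismSummary:
    """Headline dimorphism metrics for one paired comparison."""

    frac_dimorphic_edges_male: float
    frac_dimorphic_edges_female: float
    frac_dimorphic_synapses_male: float
    frac_dimorphic_synapses_female: float
    directly_dimorphic_types: set
    secondarily_dimorphic_types: set
    per_type_dimorphic_in_frac: dict
    per_type_dimorphic_out_frac: dict

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["directly_dimorphic_types"] = sorted(self.directly_dimorphic_types)
        d["secondarily_dimorphic_types"] = sorted(self.secondarily_dimorphic_types)
        return d


def dimorphism_summary(results: pd.DataFrame, annotations: pd.DataFrame,
                       secondary_min_frac: float = 0.0) -> DimorphismSummary:
    """Edge/synapse dimorphism fractions and secondarily dimorphic types.

    Fractions are computed per sex over non-noisy edges present in that
    sex (total > 0), using ``corrected_category``.  A morphologically
    isomorphic type is *secondarily dimorphic* when the dimorphic fraction
    of its incoming or outgoing synapses exceeds ``secondary_min_frac``.
    """
    col = ("corrected_category" if "corrected_category" in results.columns
           else "category")
    ok = results[results[col] != "noisy"]
    dim = ok[col] == "dimorphic"

    def fracs(sex):
        present = ok[f"{sex}_total"] > 0
        n = present.sum()
        edge_frac = float((dim & present).sum() / n) if n else 0.0
        syn = ok.loc[present, f"{sex}_total"].sum()
        syn_frac = float(ok.loc[dim & present, f"{sex}_total"].sum() / syn) if syn else 0.0
        return edge_frac, syn_frac

    em, sm = fracs("male")
    ef, sf = fracs("female")

    label = (annotations.drop_duplicates("type").set_index("type")["dimorphism"]
             .to_dict())
    directly = {t for t, l in label.items() if l in ("dimorphic", "sex_specific")}

    w = ok["male_total"] + ok["female_total"]
    in_tot = w.groupby(ok["post"]).sum()
    out_tot = w.groupby(ok["pre"]).sum()
    in_dim = w[dim].groupby(ok.loc[dim, "post"]).sum()
    out_dim = w[dim].groupby(ok.loc[dim, "pre"]).sum()
    in_frac = (in_dim.reindex(in_tot.index).fillna(0.0) / in_tot).to_dict()
    out_frac = (out_dim.reindex(out_tot.index).fillna(0.0) / out_tot).to_dict()

    secondary = set()
    for t, l in label.items():
        if l != "isomorphic" or t in directly:
            continue
        if max(in_frac.get(t, 0.0), out_frac.get(t, 0.0)) > secondary_min_frac:
            secondary.add(t)

    return DimorphismSummary(em, ef, sm, sf, directly, secondary,
                             in_frac, out_frac)
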
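"""Flow-profile clustering and behavioural compatibility scoring.

Neck-connective types (ascending/descending neurons) are embedded in 2-D
by their sensorimotor flow profiles, partitioned by k-means with the
cluster count chosen by a silhouette sweep, reordered by agglomerative
linkage of their connectivity, and scored against rule-based binary
matrices stating which modality→domain pairings are compatible with each
behaviour category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score, silhouette_score

from .labels import (DEFAULT_DOMAINS, DEFAULT_MODALITIES, LEG_DOMAINS,
                     MECHANOSENSORY_GROUP)

__all__ = [
    "ClusterModel",
    "CompatibilityMatrix",
    "embed_profiles",
    "cluster_embedding",
    "order_clusters",
    "behaviour_compatibility_matrices",
    "compatibility_scores",
    "evaluate_multilabel_auc",
]


class ConfigurationError(ValueError):
    """Raised when a behaviour rule references an unknown label."""


def embed_profiles(profiles: pd.DataFrame | np.ndarray, n_neighbors: int = 20,
                   min_dist: float = 0.0, seed: int = 0,
                   method: str = "umap") -> np.ndarray:
    """2-D neighbourhood-preserving embedding of flow profiles.

    UMAP with Euclidean input metric by default (deterministic for a fixed
    seed); ``method="pca"`` provides a fast linear alternative with the
    same interface.
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {X.shape[0]}")
    if method == "pca":
        from sklearn.decomposition import PCA
        return PCA(n_components=2, random_state=seed).fit_transform(X)
    if method != "umap":
        raise ValueError(f"unknown embedding method {method!r}")
    import umap  # deferred: numba compilation is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, metric="euclidean",
                            random_state=seed)
        return np.asarray(reducer.fit_transform(X), dtype=float)


@dataclass
class ClusterModel:
    """k-means partition of embedded types at the silhouette-optimal k."""

    coords: np.ndarray
    k: int
    labels: np.ndarray
    silhouette: float
    index: list = field(default_factory=list)  # row names (types)
    sweep: dict = field(default_factory=dict)  # k -> silhouette

    def label_map(self) -> dict:
        names = self.index if len(self.index) else range(len(self.labels))
        return {n: int(l) for n, l in zip(names, self.labels)}


def cluster_embedding(coords: np.ndarray, k_range: tuple[int, int] = (2, 60),
                      seed: int = 0, index: list | None = None) -> ClusterModel:
    """k-means over a k sweep, keeping the silhouette-maximizing partition.

    Silhouette is computed on the embedding coordinates; ties break toward
    the smallest k.  Degenerate input (all points identical) returns k=2
    with silhouette 0.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k_range[0] < 2:
        raise ValueError("k_range lower bound must be >= 2")
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(coords, coords[0]):
        labels = np.zeros(n, int)
        labels[n // 2:] = 1
        return ClusterModel(coords, 2, labels, 0.0, list(index or []), {})

    best = None
    sweep = {}
    for k in range(k_range[0], min(k_range[1], n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
        if len(np.unique(km.labels_)) < 2:
            continue
        s = float(silhouette_score(coords, km.labels_))
        sweep[k] = s
        if best is None or s > best[0] + 1e-12:
            best = (s, k, km.labels_)
    s, k, labels = best
    return ClusterModel(coords, k, labels.copy(), s, list(index or []), sweep)


def order_clusters(model: ClusterModel,
                   cluster_connectivity: np.ndarray) -> ClusterModel:
    """Renumber clusters by average-linkage leaf order of cosine distances.

    ``cluster_connectivity`` is a k × k synapse matrix; each cluster is
    described by the concatenation of its incoming and outgoing rows.
    """
    C = np.asarray(cluster_connectivity, dtype=float)
    k = model.k
    if C.shape != (k, k):
        raise ValueError(f"connectivity must be {k}x{k}, got {C.shape}")
    if k <= 2:
        order = list(range(k))
    else:
        from .graph import cosine_connectivity_similarity
        X = np.hstack([C, C.T])
        S = cosine_connectivity_similarity(X)
        zero = np.linalg.norm(X, axis=1) == 0
        S[np.ix_(zero, zero)] = 1.0  # all-zero clusters are mutually identical
        D = 1.0 - S
        np.fill_diagonal(D, 0.0)
        d = squareform(np.maximum(D, 0.0), checks=False)
        order = list(leaves_list(linkage(d, method="average")))
    rank = {old: new for new, old in enumerate(order)}
    relabeled = np.array([rank[l] for l in model.labels])
    return ClusterModel(model.coords, k, relabeled, model.silhouette,
                        model.index, model.sweep)


@dataclass
class CompatibilityMatrix:
    """Binary modality × domain compatibility matrix for one behaviour."""

    behaviour: str
    entries: pd.DataFrame  # modalities x domains, values in {0, 1}


def _require(labels, vocab, rule):
    missing = [l for l in labels if l not in vocab]
    if missing:
        raise ConfigurationError(f"rule {rule!r} references unknown labels {missing}")
    return labels


def behaviour_compatibility_matrices(modalities: list[str] | None = None,
                                     domains: list[str] | None = None
                                     ) -> list[CompatibilityMatrix]:
    """The seven rule-based behaviour compatibility matrices.

    Rules (modality → domain pairings predictive of each behaviour):

    - *vnc_sensation*: any flow originating from gustatory, tactile or
      proprioceptive modalities;
    - *escape*: flow from vision targeting the legs or wings;
    - *feeding*: flow from gustation or olfaction not targeting the
      abdominal domain, plus any flow targeting the proboscis;
    - *flight*: any flow targeting the wings or halteres;
    - *grooming*: flow from mechanosensory or tactile modalities targeting
      proboscis, neck or front leg;
    - *reproduction*: any flow targeting the abdominal domain;
    - *walking*: flow from any mechanosensory modality targeting the legs.
    """
    mods = list(modalities or DEFAULT_MODALITIES)
    doms = list(domains or DEFAULT_DOMAINS)
    legs = [d for d in LEG_DOMAINS if d in doms] or _require(LEG_DOMAINS, doms, "legs")
    mech = [m for m in MECHANOSENSORY_GROUP if m in mods] or \
        _require(MECHANOSENSORY_GROUP, mods, "mechanosensory")

    def matrix(behaviour, pairs):
        E = pd.DataFrame(0, index=mods, columns=doms, dtype=int)
        for m, d in pairs:
            E.loc[m, d] = 1
        return CompatibilityMatrix(behaviour, E)

    out = []
    out.append(matrix("vnc_sensation", [
        (m, d) for m in _require(["gustatory", "tactile", "proprioceptive"],
                                 mods, "vnc_sensation") for d in doms]))
    _require(["vision"], mods, "escape")
    _require(["wings"], doms, "escape")
    out.append(matrix("escape", [("vision", d) for d in legs + ["wings"]]))
    _require(["gustatory", "olfaction"], mods, "feeding")
    _require(["proboscis", "abdominal"], doms, "feeding")
    feeding = [(m, d) for m in ("gustatory", "olfaction") for d in doms
               if d != "abdominal"]
    feeding += [(m, "proboscis") for m in mods]
    out.append(matrix("feeding", feeding))
    _require(["wings", "halteres"], doms, "flight")
    out.append(matrix("flight", [(m, d) for m in mods for d in ("wings", "halteres")]))
    _require(["mechanosensory", "tactile"], mods, "grooming")
    _require(["proboscis", "neck", "front_leg"], doms, "grooming")
    out.append(matrix("grooming", [(m, d) for m in ("mechanosensory", "tactile")
                                   for d in ("proboscis", "neck", "front_leg")]))
    _require(["abdominal"], doms, "reproduction")
    out.append(matrix("reproduction", [(m, "abdominal") for m in mods]))
    out.append(matrix("walking", [(m, d) for m in mech for d in legs]))
    return out


def compatibility_scores(cluster_mean_flows: pd.DataFrame,
                         matrices: list[CompatibilityMatrix]) -> pd.DataFrame:
    """Score clusters against behaviours: ⟨L1-normalized flow, L1-normalized rule⟩.

    ``cluster_mean_flows`` has one row per cluster and a (modality, domain)
    MultiIndex column per pairing.  Both factors are L1-normalized before
    the elementwise product, so scores are invariant to positive rescaling
    of either.
    """
    rows = {}
    for cid, row in cluster_mean_flows.iterrows():
        v = row.to_numpy(float)
        tot = v.sum()
        if tot <= 0:
            warnings.warn(f"cluster {cid} has an all-zero flow matrix")
            rows[cid] = {mat.behaviour: 0.0 for mat in matrices}
            continue
        v = v / tot
        scores = {}
        for mat in matrices:
            flat = np.array([mat.entries.loc[m, d]
                             for (m, d) in cluster_mean_flows.columns], float)
            s = flat.sum()
            scores[mat.behaviour] = float(v @ (flat / s)) if s > 0 else 0.0
        rows[cid] = scores
    return pd.DataFrame(rows).T


def evaluate_multilabel_auc(scores: pd.DataFrame,
                            annotations: dict) -> float | None:
    """Micro-averaged ROC AUC over (cluster, behaviour) cells.

    ``annotations`` maps cluster → set of true behaviour categories.  Each
    cell is an instance with the compatibility score as decision value.
    Returns None when all cells share one label.
    """
    y, s = [], []
    for cid in scores.index:
        pos = set(annotations.get(cid, ()))
        for b in scores.columns:
            y.append(1 if b in pos else 0)
            s.append(float(scores.loc[cid, b]))
    if len(set(y)) < 2:
        return None
    return float(roc_auc_score(y, s))
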
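"""Synthetic connectome generators with planted ground truth.

Three generators emulate the statistical structure that the analysis
pipeline is designed to detect, so that every downstream stage can be
exercised and validated without any real data release:

``generate_paired_connectomes``
    A matched male/female pair of type-to-type graphs with a heavily
    right-skewed weight distribution, bilateral hemisphere replicates,
    a systematic male/female scale difference, planted dimorphic edges and
    sex-specific types.

``generate_sensorimotor_graph``
    A layered sensory → interneuron → neck → motor routing graph with
    planted modality→domain routes.

``generate_cluster_hierarchy``
    Nested partitions with designated clusters over-loaded with
    non-isomorphic types.

Every generator is a pure function of its config (same seed → identical
output) and returns a :class:`PlantedTruth` describing what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import ConnectomeGraph, EDGE_COLUMNS
from .labels import DEFAULT_DOMAINS, DEFAULT_MODALITIES

__all__ = [
    "PairedGenConfig",
    "SensorimotorGenConfig",
    "PlantedTruth",
    "ConfigError",
    "generate_paired_connectomes",
    "generate_sensorimotor_graph",
    "generate_cluster_hierarchy",
]


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators for recovery tests."""

    edge_dimorphism: dict = field(default_factory=dict)
    edge_fold: dict = field(default_factory=dict)
    type_category: dict = field(default_factory=dict)
    true_scale: float = 1.0
    planted_routes: list = field(default_factory=list)
    route_membership: dict = field(default_factory=dict)
    layer_index: dict = field(default_factory=dict)
    enriched_clusters: set = field(default_factory=set)


@dataclass
class PairedGenConfig:
    """Study conditions for the paired male/female connectome generator.

    The defaults emulate the empirical regime of paired fly-brain
    connectomes: ~5,000 cross-matched type-to-type edges whose latent
    weights are log-normal with a very heavy weak-edge tail (weak edges are
    unreliable across datasets purely through counting noise), a systematic
    male/female scale factor of 1.72 (males have more synapses), and 5% of
    edges planted as dimorphic at ≥2-fold change.  Dimorphism is planted on
    connections strong enough to be measurable (latent weight ≥ 40): with
    only two hemisphere replicates per sex, weaker planted effects are
    statistically invisible to any test.
    """

    n_types: int = 200
    n_edges: int = 5000
    frac_sex_specific_male: float = 0.03
    frac_sex_specific_female: float = 0.02
    #: extra morphologically dimorphic types beyond those implied by planted
    #: dimorphic edges (every planted edge touches >=1 dimorphic type)
    frac_dimorphic_types: float = 0.02
    frac_dimorphic_edges: float = 0.05
    dimorphic_fold_change: float = 2.0
    dimorphic_fold_max: float = 4.0
    dimorphic_min_weight: float = 40.0
    male_scale: float = 1.72
    weight_lognormal_mu: float = -0.5
    weight_lognormal_sigma: float = 3.25
    hemisphere_noise: str = "poisson"
    lognormal_noise_sigma: float = 0.3
    fru_dsx_enrichment: float = 8.0
    fru_dsx_base_rate: float = 0.04
    edges_per_sex_specific_type: int = 8
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_sex_specific_male", "frac_sex_specific_female",
                     "frac_dimorphic_types", "frac_dimorphic_edges"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_types < 10:
            raise ConfigError("n_types must be >= 10")
        if self.dimorphic_fold_change <= 1.0:
            raise ConfigError("dimorphic_fold_change must be > 1")
        if self.dimorphic_fold_max < self.dimorphic_fold_change:
            raise ConfigError("dimorphic_fold_max < dimorphic_fold_change")
        if self.male_scale <= 0:
            raise ConfigError("male_scale must be > 0")
        if self.hemisphere_noise not in ("poisson", "lognormal", "none"):
            raise ConfigError(f"unknown hemisphere_noise {self.hemisphere_noise!r}")


def _hemisphere_pair(rng: np.random.Generator, mean: np.ndarray,
                     noise: str, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw left/right hemisphere weights around half the dataset-level mean."""
    half = mean / 2.0
    if noise == "poisson":
        return rng.poisson(half).astype(float), rng.poisson(half).astype(float)
    if noise == "lognormal":
        with np.errstate(divide="ignore"):
            mu = np.where(half > 0, np.log(np.where(half > 0, half, 1.0))
                          - sigma ** 2 / 2.0, -np.inf)
        draw = lambda: np.where(half > 0, rng.lognormal(np.where(np.isfinite(mu), mu, 0.0), sigma), 0.0)
        return draw(), draw()
    return half.copy(), half.copy()


def generate_paired_connectomes(config: PairedGenConfig
                                ) -> tuple[ConnectomeGraph, ConnectomeGraph, PlantedTruth]:
    """Generate a matched male/female connectome pair with planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_types
    names = np.array([f"T{i:04d}" for i in range(n)])

    n_ssm = int(round(config.frac_sex_specific_male * n))
    n_ssf = int(round(config.frac_sex_specific_female * n))
    n_dim = int(round(config.frac_dimorphic_types * n))
    if n_ssm + n_ssf + n_dim > n:
        raise ConfigError("type category fractions exceed available types")
    perm = rng.permutation(n)
    cat = np.full(n, "isomorphic", dtype=object)
    cat[perm[:n_ssm]] = "sex_specific_male"
    cat[perm[n_ssm:n_ssm + n_ssf]] = "sex_specific_female"
    shared = np.flatnonzero(~np.char.startswith(cat.astype(str), "sex_specific"))

    # --- matched edges among cross-matched (shared) types -------------------
    n_pairs = shared.size * shared.size
    if config.n_edges > n_pairs:
        raise ConfigError("n_edges exceeds the number of ordered type pairs")
    flat = rng.choice(n_pairs, size=config.n_edges, replace=False)
    pre_idx = shared[flat // shared.size]
    post_idx = shared[flat % shared.size]
    latent = rng.lognormal(config.weight_lognormal_mu,
                           config.weight_lognormal_sigma, config.n_edges)

    k = int(round(config.frac_dimorphic_edges * config.n_edges))
    eligible = np.flatnonzero(latent >= config.dimorphic_min_weight)
    if k > eligible.size:
        raise ConfigError(
            f"cannot plant {k} dimorphic edges: only {eligible.size} edges have "
            f"latent weight >= {config.dimorphic_min_weight}")
    planted = rng.choice(eligible, size=k, replace=False)
    folds = rng.uniform(config.dimorphic_fold_change, config.dimorphic_fold_max, k)
    female_latent = latent.copy()
    female_latent[planted[:k // 2]] *= folds[:k // 2]
    female_latent[planted[k // 2:]] /= folds[k // 2:]

    # morphologically dimorphic type labels, kept consistent with the planted
    # edge-level dimorphism: every planted edge touches at least one dimorphic
    # type (labels are reused greedily so the dimorphic set stays small), plus
    # a few extra dimorphic types without planted edge effects
    incidence: dict[int, int] = {}
    for i in planted:
        for t in (pre_idx[i], post_idx[i]):
            incidence[t] = incidence.get(t, 0) + 1
    for i in planted:
        a, b = pre_idx[i], post_idx[i]
        if cat[a] != "isomorphic" or cat[b] != "isomorphic":
            continue
        pick = a if incidence[a] >= incidence[b] else b
        cat[pick] = "dimorphic"
    iso_left = np.flatnonzero(cat == "isomorphic")
    extra = min(n_dim, iso_left.size)
    if extra:
        cat[rng.choice(iso_left, size=extra, replace=False)] = "dimorphic"

    male_mean = latent * config.male_scale
    mL, mR = _hemisphere_pair(rng, male_mean, config.hemisphere_noise,
                              config.lognormal_noise_sigma)
    fL, fR = _hemisphere_pair(rng, female_latent, config.hemisphere_noise,
                              config.lognormal_noise_sigma)

    truth = PlantedTruth(true_scale=1.0 / config.male_scale)
    is_dim = np.zeros(config.n_edges, bool)
    is_dim[planted] = True
    signed_fold = np.zeros(config.n_edges)
    signed_fold[planted[:k // 2]] = folds[:k // 2]
    signed_fold[planted[k // 2:]] = -folds[k // 2:]
    for i in range(config.n_edges):
        key = (names[pre_idx[i]], names[post_idx[i]])
        truth.edge_dimorphism[key] = bool(is_dim[i])
        if is_dim[i]:
            truth.edge_fold[key] = float(signed_fold[i])
    truth.type_category = {names[i]: cat[i] for i in range(n)}

    male_rows = _edge_frame(names[pre_idx], names[post_idx], mL, mR)
    female_rows = _edge_frame(names[pre_idx], names[post_idx], fL, fR)

    # --- edges of sex-specific types ----------------------------------------
    for sex, rows in (("male", male_rows), ("female", female_rows)):
        own = np.flatnonzero(cat == f"sex_specific_{sex}")
        present = np.concatenate([shared, own])
        for t in own:
            m = config.edges_per_sex_specific_type
            partners = rng.choice(present, size=min(m, present.size), replace=False)
            w = rng.lognormal(config.weight_lognormal_mu + 2.0,
                              config.weight_lognormal_sigma / 2.0, partners.size)
            outgoing = rng.random(partners.size) < 0.5
            L, R = _hemisphere_pair(rng, w, config.hemisphere_noise,
                                    config.lognormal_noise_sigma)
            pre = np.where(outgoing, names[t], names[partners])
            post = np.where(outgoing, names[partners], names[t])
            rows.append(_edge_frame(pre, post, L, R)[0])

    # --- fru/dsx expression flags -------------------------------------------
    boosted = min(0.9, config.fru_dsx_base_rate * config.fru_dsx_enrichment)
    p_pos = np.where(cat == "isomorphic", config.fru_dsx_base_rate, boosted)
    fru = np.where(rng.random(n) < p_pos, "pos", "neg")
    dsx = np.where(rng.random(n) < p_pos, "pos", "neg")

    def annotation(sex: str) -> pd.DataFrame:
        keep = (~np.char.startswith(cat.astype(str), "sex_specific")) | (
            cat == f"sex_specific_{sex}")
        c = np.where(np.char.startswith(cat[keep].astype(str), "sex_specific"),
                     "sex_specific", cat[keep])
        return pd.DataFrame({
            "type": names[keep], "dataset": sex, "superclass": "cb_intrinsic",
            "dimorphism": c, "fru": fru[keep], "dsx": dsx[keep],
            "region": "central_brain", "modality": None, "domain": None,
        })

    male = ConnectomeGraph(_concat(male_rows), types=annotation("male"),
                           level="type", dataset="male")
    female = ConnectomeGraph(_concat(female_rows), types=annotation("female"),
                             level="type", dataset="female")
    return male, female, truth


def _edge_frame(pre, post, L, R) -> list[pd.DataFrame]:
    return [pd.DataFrame({"pre": pre, "post": post, "weight_left": L,
                          "weight_right": R, "weight_total": L + R})]


def _concat(frames: list) -> pd.DataFrame:
    flat = [f for sub in frames for f in (sub if isinstance(sub, list) else [sub])]
    df = pd.concat(flat, ignore_index=True)
    # a sex-specific partner edge may duplicate a matched pair; keep the first
    df = df.drop_duplicates(subset=["pre", "post"], keep="first")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sensorimotor routing graph
# ---------------------------------------------------------------------------

#: default planted routes, each compatible with at least one behaviour rule
DEFAULT_ROUTES = [
    ("gustatory", "proboscis"),
    ("vision", "wings"),
    ("mechanosensory", "front_leg"),
    ("proprioceptive", "hind_leg"),
    ("olfaction", "proboscis"),
    ("tactile", "neck"),
]


@dataclass
class SensorimotorGenConfig:
    """Config for the layered sensory→motor routing graph.

    The graph has five layers (sensory, brain interneurons, neck-connective
    neurons, nerve-cord interneurons, motor neurons) and is acyclic by
    construction: edges only run from lower to strictly higher layers.  Each
    planted (modality, domain) route is a dedicated chain of interneurons
    carrying strong weights; background edges are sparse and weak.
    """

    modalities: tuple = tuple(DEFAULT_MODALITIES)
    domains: tuple = tuple(DEFAULT_DOMAINS)
    routes: tuple = tuple(DEFAULT_ROUTES)
    n_sensory_per_modality: int = 6
    n_motor_per_domain: int = 5
    n_brain_per_route: int = 3
    n_neck_per_route: int = 6
    n_vnc_per_route: int = 3
    n_background_interneurons: int = 12
    n_background_neck: int = 30
    route_strength: float = 60.0
    background_density: float = 0.03
    background_strength: float = 4.0
    feedback_density: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.modalities or not self.domains:
            raise ConfigError("need at least one modality and one domain")
        for m, d in self.routes:
            if m not in self.modalities:
                raise ConfigError(f"route modality {m!r} not in vocabulary")
            if d not in self.domains:
                raise ConfigError(f"route domain {d!r} not in vocabulary")
        if not 0.0 <= self.background_density <= 1.0:
            raise ConfigError("background_density outside [0, 1]")


def generate_sensorimotor_graph(config: SensorimotorGenConfig
                                ) -> tuple[ConnectomeGraph, PlantedTruth]:
    """Generate a layered routing graph with planted modality→domain routes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth(planted_routes=list(config.routes))

    nodes: list[dict] = []
    layer: dict[str, int] = {}

    def add(name, superclass, lay, modality=None, domain=None, route=None):
        nodes.append({"type": name, "superclass": superclass,
                      "modality": modality, "domain": domain})
        layer[name] = lay
        if route is not None:
            truth.route_membership[name] = route

    sensory: dict[str, list[str]] = {}
    for m in config.modalities:
        sensory[m] = [f"SN_{m}_{i}" for i in range(config.n_sensory_per_modality)]
        for s in sensory[m]:
            add(s, "cb_sensory", 0, modality=m)
    motor: dict[str, list[str]] = {}
    for d in config.domains:
        motor[d] = [f"MN_{d}_{i}" for i in range(config.n_motor_per_domain)]
        for t in motor[d]:
            add(t, "motor", 4, domain=d)

    edges: dict[tuple, float] = {}

    def connect(u, v, w):
        if u != v and w > 0:
            edges[(u, v)] = edges.get((u, v), 0.0) + float(w)

    for r, (m, d) in enumerate(config.routes):
        brain = [f"IN_r{r}_{i}" for i in range(config.n_brain_per_route)]
        neck = [f"DN_r{r}_{i}" for i in range(config.n_neck_per_route)]
        vnc = [f"VN_r{r}_{i}" for i in range(config.n_vnc_per_route)]
        for x in brain:
            add(x, "cb_intrinsic", 1, route=(m, d))
        for i, x in enumerate(neck):
            add(x, "descending_neuron" if i % 2 == 0 else "ascending_neuron",
                2, route=(m, d))
        for x in vnc:
            add(x, "vnc_intrinsic", 3, route=(m, d))
        jitter = lambda: config.route_strength * rng.uniform(0.8, 1.2)
        for s in sensory[m]:
            for b in brain:
                connect(s, b, jitter())
        for b in brain:
            for nk in neck:
                connect(b, nk, jitter())
        for nk in neck:
            for v in vnc:
                connect(nk, v, jitter())
        for v in vnc:
            for t in motor[d]:
                connect(v, t, jitter())

    for i in range(config.n_background_interneurons):
        add(f"IN_bg_{i}", "cb_intrinsic", 1)
    for i in range(config.n_background_neck):
        add(f"DN_bg_{i}", "descending_neuron" if i % 2 == 0 else "ascending_neuron", 2)
    for i in range(config.n_background_interneurons):
        add(f"VN_bg_{i}", "vnc_intrinsic", 3)

    names = [n["type"] for n in nodes]
    if config.background_density > 0:
        for u in names:
            for v in names:
                if layer[u] < layer[v] and rng.random() < config.background_density:
                    connect(u, v, 1 + rng.poisson(config.background_strength))
    if config.feedback_density > 0:
        for u in names:
            for v in names:
                if layer[u] > layer[v] and rng.random() < config.feedback_density:
                    connect(u, v, 1 + rng.poisson(config.background_strength))

    truth.layer_index = dict(layer)
    rows = pd.DataFrame(
        [{"pre": u, "post": v, "weight_left": w / 2, "weight_right": w / 2,
          "weight_total": w} for (u, v), w in sorted(edges.items())],
        columns=EDGE_COLUMNS)
    types = pd.DataFrame(nodes)
    types["dataset"] = "male"
    types["dimorphism"] = "isomorphic"
    types["fru"] = "unknown"
    types["dsx"] = "unknown"
    types["region"] = "central_brain"
    graph = ConnectomeGraph(rows, types=types, level="type", dataset="male")
    return graph, truth


# ---------------------------------------------------------------------------
# nested cluster hierarchy with planted enrichment
# ---------------------------------------------------------------------------

def generate_cluster_hierarchy(n_types: int = 400, levels: int = 3,
                               enriched: dict | None = None, seed: int = 0
                               ) -> tuple[list[dict], PlantedTruth]:
    """Nested partitions with clusters over-loaded with non-isomorphic types.

    Parameters
    ----------
    enriched:
        ``{"n_clusters": int, "odds": float, "frac_noniso": float}`` —
        number of finest-level clusters to enrich, the placement odds
        multiplier for non-isomorphic types, and the overall fraction of
        non-isomorphic types.  ``n_clusters=0`` disables planting.

    Returns
    -------
    assignments:
        One ``{type: cluster_id}`` map per level; level 0 is the finest and
        each level-k cluster maps into exactly one level-(k+1) cluster.
    truth:
        ``type_category`` (isomorphic/noniso per type) and
        ``enriched_clusters`` as a set of ``(level, cluster_id)`` pairs for
        the finest level.
    """
    if levels < 1:
        raise ConfigError("levels must be >= 1")
    opts = {"n_clusters": 4, "odds": 25.0, "frac_noniso": 0.15}
    opts.update(enriched or {})
    rng = np.random.default_rng(seed)
    names = [f"T{i:04d}" for i in range(n_types)]

    n_noniso = int(round(opts["frac_noniso"] * n_types))
    noniso = set(rng.choice(n_types, size=n_noniso, replace=False).tolist())
    categories = {names[i]: ("noniso" if i in noniso else "isomorphic")
                  for i in range(n_types)}

    k0 = max(4, n_types // 12)
    n_enr = int(opts["n_clusters"])
    if n_enr > k0:
        raise ConfigError(f"cannot enrich {n_enr} of {k0} clusters")
    if n_enr > 0 and n_noniso == 0:
        raise ConfigError("enrichment requested but no non-isomorphic types")
    enr = set(rng.choice(k0, size=n_enr, replace=False).tolist())

    # non-isomorphic types fall into an enriched cluster with odds-boosted
    # probability; the enriched-bound ones are dealt round-robin so that all
    # planted clusters are comparably over-loaded
    non_enr = [c for c in range(k0) if c not in enr]
    share = (opts["odds"] * n_enr) / (opts["odds"] * n_enr + len(non_enr)) \
        if n_enr else 0.0
    assign0 = {}
    enr_cycle = list(enr)
    deal = 0
    for i, name in enumerate(names):
        if i in noniso and n_enr and rng.random() < share:
            assign0[name] = enr_cycle[deal % n_enr]
            deal += 1
        elif i in noniso and non_enr:
            assign0[name] = int(rng.choice(non_enr))
        else:
            assign0[name] = int(rng.choice(k0))

    assignments = [assign0]
    current = list(range(k0))
    contains_enr = {c: (c in enr) for c in current}
    for _ in range(1, levels):
        n_next = max(1, len(current) // 2)
        # enriched clusters merge with each other first so that planted
        # enrichment persists at coarser levels
        order = sorted(current, key=lambda c: (not contains_enr[c], rng.random()))
        mapping = {c: min(i // 2, n_next - 1) for i, c in enumerate(order)}
        prev = assignments[-1]
        assignments.append({t: mapping[c] for t, c in prev.items()})
        nxt = sorted(set(mapping.values()))
        contains_enr = {c2: any(contains_enr[c] for c in current if mapping[c] == c2)
                        for c2 in nxt}
        current = nxt

    truth = PlantedTruth(type_category=categories,
                         enriched_clusters={(0, c) for c in enr})
    return assignments, truth
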
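"""Sensory-to-motor maximum-flow analysis.

For each pairing of a sensory modality (sources) and a motor domain
(sinks), a capacity graph is built from input-normalized connectivity
(each edge's capacity is the fraction of its target's total input),
discretized to integers in [0, 10000].  A pseudo-source feeds every source
neuron and every sink neuron feeds a pseudo-sink through unit-capacity
edges, so the maximum flow is bounded by min(#sources, #sinks).  Flow is
computed exactly with Dinic's algorithm and renormalized to [0, 1].

Per-neuron summaries across all pairings: mean through-flow per modality
and per domain (preference), max/sum concentration of those vectors
(specificity), and mean fraction of a neuron's synaptic capacity in use
(utilization).  A real-valued pseudo-layering orders neurons so that each
sits one unit deeper than the flow-weighted mean of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.flow import dinitz

from .graph import ConnectomeGraph, input_normalize

__all__ = [
    "CapacityGraph",
    "FlowResult",
    "SensorimotorProfile",
    "build_capacity_graph",
    "max_flow",
    "flow_profile",
    "pseudo_layers",
    "PSEUDO_SOURCE",
    "PSEUDO_SINK",
]

PSEUDO_SOURCE = "__source__"
PSEUDO_SINK = "__sink__"
SCALE = 10000


@dataclass
class CapacityGraph:
    """Integer-capacity graph for one (modality, domain) pairing."""

    capacities: dict  # (u, v) -> int in [0, SCALE]
    sources: list
    sinks: list
    scale: int = SCALE
    pair: tuple = ("", "")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(PSEUDO_SOURCE)
        g.add_node(PSEUDO_SINK)
        for (u, v), c in self.capacities.items():
            g.add_edge(u, v, capacity=int(c))
        return g


@dataclass
class FlowResult:
    """Exact max-flow assignment for one pairing, renormalized to [0, 1]."""

    pair: tuple
    value: float
    edge_flow: dict        # (u, v) -> flow in [0, 1], interior edges only
    node_throughflow: dict  # neuron -> inflow under the assignment
    sources: list = field(default_factory=list)
    sinks: list = field(default_factory=list)


def build_capacity_graph(graph: ConnectomeGraph, modality: str, domain: str,
                         scale: int = SCALE) -> CapacityGraph:
    """Capacity graph from input-normalized weights for one pairing.

    Sources are sensory neurons of ``modality``; sinks are motor neurons of
    ``domain``.  Inputs to sources and outputs from sinks are removed;
    pseudo edges carry unit capacity (= ``scale``).
    """
    if graph.types is None:
        raise ValueError("flow analysis requires node annotations")
    t = graph.types
    sources = sorted(t.loc[(t["modality"] == modality)
                           & (t["superclass"].str.contains("sensory")), "type"])
    sinks = sorted(t.loc[(t["domain"] == domain)
                         & (t["superclass"] == "motor"), "type"])
    if not sources:
        raise ValueError(f"no sensory neurons with modality {modality!r}")
    if not sinks:
        raise ValueError(f"no motor neurons with domain {domain!r}")
    src_set, sink_set = set(sources), set(sinks)

    norm = input_normalize(graph)
    caps: dict[tuple, int] = {}
    for (u, v), c in norm.items():
        if v in src_set or u in sink_set:
            continue  # inputs to sources and outputs from sinks are ignored
        ic = int(np.floor(c * scale + 0.5))  # round half up
        if ic > 0:
            caps[(u, v)] = ic
    for s in sources:
        caps[(PSEUDO_SOURCE, s)] = scale
    for s in sinks:
        caps[(s, PSEUDO_SINK)] = scale
    return CapacityGraph(caps, sources, sinks, scale, (modality, domain))


def max_flow(cg: CapacityGraph) -> FlowResult:
    """Exact integer max flow (Dinic's algorithm), renormalized by the scale."""
    g = cg.to_networkx()
    R = dinitz(g, PSEUDO_SOURCE, PSEUDO_SINK)
    value = R.graph["flow_value"]
    edge_flow = {}
    through = {}
    for u, v, d in R.edges(data=True):
        f = d.get("flow", 0)
        if f <= 0:
            continue
        if u != PSEUDO_SOURCE and v != PSEUDO_SINK:
            edge_flow[(u, v)] = f / cg.scale
        if v != PSEUDO_SINK:
            through[v] = through.get(v, 0) + f
    node_throughflow = {n: f / cg.scale for n, f in through.items()}
    return FlowResult(cg.pair, value / cg.scale, edge_flow, node_throughflow,
                      cg.sources, cg.sinks)


@dataclass
class SensorimotorProfile:
    """Per-neuron flow summaries across all (modality, domain) pairings."""

    flow_matrix: pd.DataFrame          # neurons x (modality, domain) MultiIndex
    sensory_preference: pd.DataFrame   # neurons x modalities (mean over domains)
    motor_preference: pd.DataFrame     # neurons x domains (mean over modalities)
    sensory_specificity: pd.Series
    motor_specificity: pd.Series
    combined_specificity: pd.Series
    utilization: pd.Series
    flows: dict = field(default_factory=dict)  # (modality, domain) -> FlowResult


def _specificity(df: pd.DataFrame) -> pd.Series:
    s = df.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = df.max(axis=1) / s.where(s > 0)
    return out.fillna(0.0)


def flow_profile(graph: ConnectomeGraph, modalities: list[str],
                 domains: list[str], scale: int = SCALE) -> SensorimotorProfile:
    """Run max flow for every pairing and summarize per-neuron through-flow."""
    flows: dict[tuple, FlowResult] = {}
    for m in modalities:
        for d in domains:
            cg = build_capacity_graph(graph, m, d, scale=scale)
            flows[(m, d)] = max_flow(cg)

    nodes = sorted(set(graph.nodes) | set(graph.types["type"]))
    cols = pd.MultiIndex.from_product([modalities, domains],
                                      names=["modality", "domain"])
    M = pd.DataFrame(0.0, index=nodes, columns=cols)
    for (m, d), fr in flows.items():
        for n, f in fr.node_throughflow.items():
            M.loc[n, (m, d)] = f

    sens = M.T.groupby(level="modality").mean().T[list(modalities)]
    mot = M.T.groupby(level="domain").mean().T[list(domains)]

    # node capacity: min(total in-capacity, total out-capacity) on the
    # input-normalized base graph, with pseudo edges giving sources unit
    # in-capacity and sinks unit out-capacity
    norm = input_normalize(graph)
    in_cap = pd.Series(0.0, index=nodes)
    out_cap = pd.Series(0.0, index=nodes)
    for (u, v), c in norm.items():
        in_cap[v] += c
        out_cap[u] += c
    t = graph.types
    sensory = set(t.loc[t["superclass"].str.contains("sensory"), "type"])
    motor = set(t.loc[t["superclass"] == "motor", "type"])
    for n in nodes:
        if n in sensory:
            in_cap[n] = max(in_cap[n], 1.0)
        if n in motor:
            out_cap[n] = max(out_cap[n], 1.0)
    cap = pd.concat([in_cap, out_cap], axis=1).min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        util = (M.div(cap.where(cap > 0), axis=0)).clip(upper=1.0).mean(axis=1)
    util = util.fillna(0.0)

    return SensorimotorProfile(
        flow_matrix=M,
        sensory_preference=sens,
        motor_preference=mot,
        sensory_specificity=_specificity(sens),
        motor_specificity=_specificity(mot),
        combined_specificity=_specificity(M),
        utilization=util,
        flows=flows,
    )


def _cancel_flow_cycles(edge_flow: dict) -> dict:
    """Remove circulation from a flow assignment so it forms a DAG."""
    flow = dict(edge_flow)
    while True:
        g = nx.DiGraph(list(flow))
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return flow
        fmin = min(flow[(u, v)] for u, v, *_ in
                   [(e[0], e[1]) for e in cycle])
        for u, v, *_ in cycle:
            flow[(u, v)] -= fmin
            if flow[(u, v)] <= 1e-12:
                del flow[(u, v)]


@dataclass
class LayerVector:
    """Real-valued flow depth per neuron (sources at 0)."""

    layers: dict
    flow_adjacency: pd.DataFrame


def pseudo_layers(flow: FlowResult) -> LayerVector:
    """Solve the pseudo-layering equation (l + 1) F = l on a flow DAG.

    F is the input-normalized flow adjacency (each column of inflow sums
    to 1); nodes without flow input sit at layer 0 and every other node is
    one unit deeper than the flow-weighted mean of its inputs.  Solved by a
    direct linear solve of l (F − I) = −1 F, with a pseudo-inverse
    fallback for singular systems.
    """
    edge_flow = _cancel_flow_cycles(flow.edge_flow)
    nodes = sorted({u for u, _ in edge_flow} | {v for _, v in edge_flow})
    if not nodes:
        return LayerVector({}, pd.DataFrame())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    F = np.zeros((n, n))
    for (u, v), f in edge_flow.items():
        F[idx[u], idx[v]] = f
    col = F.sum(axis=0)
    nz = col > 0
    F[:, nz] /= col[nz]

    A = (F - np.eye(n)).T
    b = -F.sum(axis=0)  # (1·F) per column
    try:
        l = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        l, *_ = np.linalg.lstsq(A, b, rcond=None)
    l[~nz] = 0.0
    Fdf = pd.DataFrame(F, index=nodes, columns=nodes)
    return LayerVector({nd: float(l[idx[nd]]) for nd in nodes}, Fdf)
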
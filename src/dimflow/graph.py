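"""Core connectome-graph containers and elementary connectivity operations.

A connectome is represented as a directed, weighted graph whose nodes are
either individual neurons or cell types and whose edge weights are synapse
counts, split into left- and right-hemisphere contributions.  Edge tables
and annotation tables are plain :class:`pandas.DataFrame` objects wrapped in
:class:`ConnectomeGraph` together with light validation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeGraph",
    "ValidationError",
    "read_edge_table",
    "write_edge_table",
    "input_normalize",
    "output_normalize",
    "split_weights_by_side",
    "effective_connectivity",
    "cosine_connectivity_similarity",
    "to_networkx",
]

EDGE_COLUMNS = ["pre", "post", "weight_left", "weight_right", "weight_total"]

#: annotation table columns (type level)
TYPE_COLUMNS = ["type", "dataset", "superclass", "dimorphism", "fru", "dsx",
                "region", "modality", "domain"]

#: neuron table columns (neuron level)
NEURON_COLUMNS = ["body_id", "type", "dataset", "soma_side", "root_side",
                  "superclass", "modality", "domain"]


class ValidationError(ValueError):
    """Raised when an edge or annotation table violates a graph invariant."""


@dataclass
class ConnectomeGraph:
    """Directed weighted connectome graph for a single dataset.

    Parameters
    ----------
    edges:
        One row per directed ``pre -> post`` connection with per-hemisphere
        synapse counts (``weight_left``, ``weight_right``) and their sum
        ``weight_total``.  Weights may be fractional (after midline splitting
        or cross-dataset scaling).
    types:
        Optional type annotation table (``type``, ``superclass``,
        ``dimorphism``, ``fru``, ``dsx``, ``region``, ``modality``,
        ``domain``).
    neurons:
        Optional neuron table for neuron-level graphs (``body_id``, ``type``,
        ``soma_side``, ``root_side``, ``superclass``).
    level:
        ``"neuron"`` or ``"type"``.
    """

    edges: pd.DataFrame
    types: pd.DataFrame | None = None
    neurons: pd.DataFrame | None = None
    level: str = "type"
    dataset: str | None = None

    def __post_init__(self) -> None:
        self.edges = _validate_edges(self.edges)
        if self.level not in ("neuron", "type"):
            raise ValidationError(f"unknown graph level {self.level!r}")
        if self.neurons is not None and "body_id" in self.neurons.columns:
            dup = self.neurons["body_id"].duplicated()
            if dup.any():
                raise ValidationError(
                    f"duplicate body_ids: {sorted(self.neurons['body_id'][dup])[:5]}"
                )

    @property
    def nodes(self) -> list:
        return sorted(set(self.edges["pre"]) | set(self.edges["post"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_synapses(self) -> float:
        return float(self.edges["weight_total"].sum())

    def copy(self) -> "ConnectomeGraph":
        return ConnectomeGraph(
            self.edges.copy(),
            None if self.types is None else self.types.copy(),
            None if self.neurons is None else self.neurons.copy(),
            self.level,
            self.dataset,
        )


def _validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("pre", "post") if c not in edges.columns]
    if missing:
        raise ValidationError(f"edge table missing columns: {missing}")
    edges = edges.copy()
    for col in ("weight_left", "weight_right"):
        if col not in edges.columns:
            raise ValidationError(f"edge table missing columns: ['{col}']")
    if "weight_total" not in edges.columns:
        edges["weight_total"] = edges["weight_left"] + edges["weight_right"]
    for col in ("weight_left", "weight_right", "weight_total"):
        bad = np.flatnonzero(edges[col].to_numpy() < 0)
        if bad.size:
            raise ValidationError(f"negative {col} at row {int(bad[0])}")
    tot = edges["weight_left"] + edges["weight_right"]
    if not np.allclose(tot, edges["weight_total"], rtol=0, atol=1e-9):
        bad = int(np.flatnonzero(~np.isclose(tot, edges["weight_total"]))[0])
        raise ValidationError(f"weight_total != left+right at row {bad}")
    dup = edges.duplicated(subset=["pre", "post"])
    if dup.any():
        pair = edges.loc[dup.idxmax(), ["pre", "post"]].tolist()
        raise ValidationError(f"duplicate edge {tuple(pair)}")
    # absent and zero are equivalent downstream; drop zero-weight rows
    edges = edges[edges["weight_total"] > 0].reset_index(drop=True)
    return edges


def read_edge_table(path: str | Path, level: str = "type",
                    types: pd.DataFrame | None = None,
                    dataset: str | None = None) -> ConnectomeGraph:
    """Read a CSV/TSV edge table into a :class:`ConnectomeGraph`.

    The file must have a header with columns ``pre``, ``post``,
    ``weight_left``, ``weight_right``; ``weight_total`` is optional and is
    filled in as ``left + right`` when absent.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    with open(path) as fh:
        head = fh.readline()
    if "\t" in head:
        sep = "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("pre", "post", "weight_left", "weight_right")
               if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return ConnectomeGraph(df, types=types, level=level, dataset=dataset)


def write_edge_table(graph: ConnectomeGraph, path: str | Path) -> None:
    """Write the edge table as comma-separated UTF-8 text."""
    graph.edges[EDGE_COLUMNS].to_csv(path, index=False)


def _normalize(edges: pd.DataFrame, by: str) -> dict[tuple, float]:
    sums = edges.groupby(by)["weight_total"].transform("sum")
    vals = edges["weight_total"] / sums
    return {
        (pre, post): float(v)
        for pre, post, v in zip(edges["pre"], edges["post"], vals)
    }


def input_normalize(graph: ConnectomeGraph) -> dict[tuple, float]:
    """Fraction of the postsynaptic node's total input carried by each edge.

    For edge A→B the value is ``w(A→B) / Σ_X w(X→B)``; values into each post
    node sum to one.  Nodes with no input simply do not appear as targets.
    """
    if graph.n_edges == 0:
        raise ValidationError("graph has no edges")
    return _normalize(graph.edges, "post")


def output_normalize(graph: ConnectomeGraph) -> dict[tuple, float]:
    """Fraction of the presynaptic node's total output carried by each edge."""
    if graph.n_edges == 0:
        raise ValidationError("graph has no edges")
    return _normalize(graph.edges, "pre")


def split_weights_by_side(neuron_graph: ConnectomeGraph) -> ConnectomeGraph:
    """Pool a neuron-level graph to type level, splitting weights by hemisphere.

    Each neuron-to-neuron weight is attributed to the left or right
    hemisphere using the source neuron's soma side (entry-nerve side for
    sensory neurons, carried in ``root_side``).  Unpaired medial sources use
    the target's side; if both are medial the weight is split evenly.
    """
    if neuron_graph.level != "neuron" or neuron_graph.neurons is None:
        raise ValidationError("side splitting requires a neuron-level graph")
    neu = neuron_graph.neurons.set_index("body_id")
    missing = []
    side = {}
    for body_id, row in neu.iterrows():
        s = row.get("root_side") if str(row.get("superclass", "")).endswith("sensory") else None
        if s is None or (isinstance(s, float) and math.isnan(s)):
            s = row.get("soma_side")
        if s not in ("L", "R", "M"):
            missing.append(body_id)
        side[body_id] = s
    if missing:
        raise ValidationError(f"neurons missing side annotation: {missing[:10]}")

    typ = neu["type"].to_dict()
    acc: dict[tuple, list[float]] = {}
    for pre, post, w in zip(neuron_graph.edges["pre"], neuron_graph.edges["post"],
                            neuron_graph.edges["weight_total"]):
        s = side[pre]
        if s == "M":
            s = side[post]
        key = (typ[pre], typ[post])
        lr = acc.setdefault(key, [0.0, 0.0])
        if s == "L":
            lr[0] += w
        elif s == "R":
            lr[1] += w
        else:  # both endpoints medial: split evenly
            lr[0] += w / 2.0
            lr[1] += w / 2.0
    rows = [
        {"pre": k[0], "post": k[1], "weight_left": v[0], "weight_right": v[1],
         "weight_total": v[0] + v[1]}
        for k, v in sorted(acc.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    ]
    return ConnectomeGraph(pd.DataFrame(rows, columns=EDGE_COLUMNS),
                           types=neuron_graph.types, level="type",
                           dataset=neuron_graph.dataset)


def effective_connectivity(graph: ConnectomeGraph, sources: Iterable,
                           targets: Iterable, max_hops: int = 2
                           ) -> list[tuple]:
    """Direct and two-hop path scores between source and target nodes.

    A direct edge scores its connection weight; a two-hop path scores the
    square root of the product of its two weights.  Returns one record
    ``(source, target, path, score)`` per qualifying path.
    """
    if max_hops not in (1, 2):
        raise ValueError(f"max_hops must be 1 or 2, got {max_hops}")
    sources, targets = set(sources), set(targets)
    w = {(a, b): t for a, b, t in zip(graph.edges["pre"], graph.edges["post"],
                                      graph.edges["weight_total"])}
    out: dict = {}
    for (a, b) in w:
        out.setdefault(a, []).append(b)
    records = []
    for s in sorted(sources, key=str):
        for t in sorted(targets, key=str):
            if (s, t) in w:
                records.append((s, t, (s, t), float(w[s, t])))
            if max_hops == 2:
                for mid in out.get(s, []):
                    if mid in (s, t):
                        continue
                    if (mid, t) in w:
                        score = math.sqrt(w[s, mid] * w[mid, t])
                        records.append((s, t, (s, mid, t), score))
    return records


def cosine_connectivity_similarity(profiles: np.ndarray | pd.DataFrame
                                   ) -> np.ndarray:
    """Pairwise cosine similarity between connectivity profile rows.

    Zero rows have similarity 0 to everything (including themselves) by
    convention; nonzero rows have unit self-similarity.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two rows")
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe[:, None]
    S = U @ U.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    return np.clip(S, -1.0, 1.0)


def to_networkx(graph: ConnectomeGraph, weight_col: str = "weight_total"
                ) -> nx.DiGraph:
    """Convert to a :class:`networkx.DiGraph` with a ``weight`` attribute."""
    g = nx.DiGraph()
    for pre, post, w in zip(graph.edges["pre"], graph.edges["post"],
                            graph.edges[weight_col]):
        g.add_edge(pre, post, weight=float(w))
    return g
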
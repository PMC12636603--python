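"""Probabilistic graph-traversal layering from sensory seeds.

Starting from a seed pool (layer 1), each round every untraversed neuron
whose traversed neurons supply a fraction f of its total input is added
independently with probability min(1, f / threshold): a neuron receiving
30% or more of its inputs from the traversed pool (at the default
threshold) is traversed with certainty.  Repeating the stochastic
traversal many times yields a mean layer per neuron — a distance-from-
sensory measure that respects connection strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ConnectomeGraph

__all__ = ["TraversalConfig", "LayerResult", "traverse_once", "mean_layers"]


@dataclass
class TraversalConfig:
    threshold: float = 0.3
    n_iter: int = 10000
    max_rounds: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _input_fraction_matrix(graph: ConnectomeGraph) -> tuple[list, np.ndarray]:
    """W[i, j] = fraction of node j's total input contributed by node i."""
    nodes = graph.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for pre, post, w in zip(graph.edges["pre"], graph.edges["post"],
                            graph.edges["weight_total"]):
        W[idx[pre], idx[post]] += w
    tot = W.sum(axis=0)
    nz = tot > 0
    W[:, nz] /= tot[nz]
    return nodes, W


def traverse_once(graph: ConnectomeGraph, seeds, config: TraversalConfig,
                  rng: np.random.Generator) -> dict:
    """One stochastic traversal; returns neuron → 1-based layer (unreached
    neurons are absent from the map)."""
    config.validate()
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    nodes, W = _input_fraction_matrix(graph)
    idx = {n: i for i, n in enumerate(nodes)}
    layers = np.zeros(len(nodes), dtype=int)
    state = np.zeros(len(nodes), dtype=bool)
    for s in seeds:
        if s in idx:
            state[idx[s]] = True
            layers[idx[s]] = 1
    max_rounds = config.max_rounds or len(nodes)
    for r in range(2, max_rounds + 2):
        if state.all():
            break
        f = state.astype(float) @ W
        prob = np.minimum(1.0, f / config.threshold)
        prob[state] = 0.0
        add = rng.random(len(nodes)) < prob
        if not add.any():
            if (prob == 0).all():
                break
            continue
        layers[add] = r
        state |= add
    return {n: int(layers[idx[n]]) for n in nodes if state[idx[n]]}


@dataclass
class LayerResult:
    mean_layer: dict
    sd_layer: dict
    unreached_frac: dict


def mean_layers(graph: ConnectomeGraph, seeds, config: TraversalConfig
                ) -> LayerResult:
    """Mean and SD of the traversal layer over ``config.n_iter`` repeats.

    Means and SDs are computed over the runs in which a neuron was reached;
    the fraction of runs in which it was never reached is reported
    separately.  All iterations are simulated simultaneously as a batched
    Bernoulli process, so the default 10,000 repeats are cheap.
    """
    config.validate()
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    nodes, W = _input_fraction_matrix(graph)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rng = np.random.default_rng(config.seed)
    n_iter = config.n_iter
    state = np.zeros((n_iter, n), dtype=bool)
    layers = np.zeros((n_iter, n), dtype=np.int32)
    seed_idx = [idx[s] for s in seeds if s in idx]
    state[:, seed_idx] = True
    layers[:, seed_idx] = 1
    Wf = W.astype(np.float32)
    max_rounds = config.max_rounds or n
    for r in range(2, max_rounds + 2):
        if state.all():
            break
        f = state.astype(np.float32) @ Wf
        prob = np.minimum(1.0, f / config.threshold)
        prob[state] = 0.0
        add = rng.random((n_iter, n), dtype=np.float32) < prob
        if not add.any():
            if (prob == 0).all():
                break
            continue
        layers[add] = r
        state |= add

    reached = layers > 0
    cnt = reached.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, layers.sum(axis=0) / np.maximum(cnt, 1), np.nan)
        sq = np.where(reached, (layers - mean[None, :]) ** 2, 0.0).sum(axis=0)
        sd = np.where(cnt > 0, np.sqrt(sq / np.maximum(cnt, 1)), np.nan)
    unreached = 1.0 - cnt / n_iter
    return LayerResult(
        mean_layer={nd: float(mean[i]) for nd, i in idx.items() if cnt[i] > 0},
        sd_layer={nd: float(sd[i]) for nd, i in idx.items() if cnt[i] > 0},
        unreached_frac={nd: float(unreached[i]) for nd, i in idx.items()},
    )
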
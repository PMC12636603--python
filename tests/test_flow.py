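"""Max-flow analysis: capacity construction, Dinic vs oracle, layering."""

import numpy as np
import pytest

from dimflow.flow import (PSEUDO_SINK, PSEUDO_SOURCE, CapacityGraph,
                          build_capacity_graph, flow_profile, max_flow,
                          pseudo_layers)

from conftest import make_graph


def annotated_graph(edges, sensory, motor):
    """Graph whose types table marks ``sensory`` {name: modality} and
    ``motor`` {name: domain}."""
    import pandas as pd
    g = make_graph(edges)
    names = sorted(set(g.edges["pre"]) | set(g.edges["post"]))
    rows = []
    for n in names:
        rows.append({"type": n,
                     "superclass": ("cb_sensory" if n in sensory else
                                    "motor" if n in motor else "cb_intrinsic"),
                     "modality": sensory.get(n), "domain": motor.get(n)})
    g.types = pd.DataFrame(rows)
    return g


def edmonds_karp_oracle(capacities, s, t):
    """Independent augmenting-path (BFS) max-flow oracle on integer capacities."""
    residual = {}
    adj = {}
    for (u, v), c in capacities.items():
        residual[(u, v)] = residual.get((u, v), 0) + int(c)
        residual.setdefault((v, u), 0)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    flow = 0
    while True:
        parent = {s: None}
        queue = [s]
        while queue and t not in parent:
            u = queue.pop(0)
            for v in adj.get(u, ()):
                if v not in parent and residual.get((u, v), 0) > 0:
                    parent[v] = u
                    queue.append(v)
        if t not in parent:
            return flow
        path = []
        v = t
        while parent[v] is not None:
            path.append((parent[v], v))
            v = parent[v]
        aug = min(residual[e] for e in path)
        for (u, v) in path:
            residual[(u, v)] -= aug
            residual[(v, u)] += aug
        flow += aug


def random_capacity_graph(rng, n_nodes):
    nodes = [f"n{i}" for i in range(n_nodes)]
    caps = {}
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < 0.35:
                caps[(u, v)] = int(rng.integers(1, 10000))
    n_src = int(rng.integers(1, max(2, n_nodes // 3)))
    n_snk = int(rng.integers(1, max(2, n_nodes // 3)))
    sources = nodes[:n_src]
    sinks = nodes[-n_snk:]
    for s in sources:
        caps[(PSEUDO_SOURCE, s)] = 10000
        caps.pop((s, PSEUDO_SOURCE), None)
    for t in sinks:
        caps[(t, PSEUDO_SINK)] = 10000
    caps = {(u, v): c for (u, v), c in caps.items()
            if v not in sources and u not in sinks
            or u == PSEUDO_SOURCE or v == PSEUDO_SINK}
    return CapacityGraph(caps, sources, sinks)


class TestCapacityGraph:
    def test_sole_input_saturates_scale(self):
        g = annotated_graph([("s", "a", 10, 0), ("a", "m", 3, 0)],
                            {"s": "olf"}, {"m": "leg"})
        cg = build_capacity_graph(g, "olf", "leg")
        assert cg.capacities[("s", "a")] == 10000
        assert cg.capacities[("a", "m")] == 10000

    def test_rounding_of_fractional_input(self):
        g = annotated_graph([("s", "a", 1, 0), ("x", "a", 2, 0),
                             ("a", "m", 1, 0)], {"s": "olf"}, {"m": "leg"})
        cg = build_capacity_graph(g, "olf", "leg")
        assert cg.capacities[("s", "a")] == 3333
        assert cg.capacities[("x", "a")] == 6667

    def test_inputs_to_sources_and_outputs_from_sinks_removed(self):
        g = annotated_graph([("a", "s", 5, 0), ("s", "b", 5, 0),
                             ("b", "m", 5, 0), ("m", "c", 5, 0)],
                            {"s": "olf"}, {"m": "leg"})
        cg = build_capacity_graph(g, "olf", "leg")
        assert ("a", "s") not in cg.capacities
        assert ("m", "c") not in cg.capacities

    def test_missing_label_raises(self):
        g = annotated_graph([("s", "m", 1, 0)], {"s": "olf"}, {"m": "leg"})
        with pytest.raises(ValueError, match="vision"):
            build_capacity_graph(g, "vision", "leg")


class TestMaxFlow:
    def test_single_path_bottleneck(self):
        cg = CapacityGraph({(PSEUDO_SOURCE, "s"): 10000, ("s", "a"): 5000,
                            ("a", "t"): 10000, ("t", PSEUDO_SINK): 10000},
                           ["s"], ["t"])
        assert max_flow(cg).value == pytest.approx(0.5)

    def test_disconnected_value_zero(self):
        cg = CapacityGraph({(PSEUDO_SOURCE, "s"): 10000,
                            ("t", PSEUDO_SINK): 10000}, ["s"], ["t"])
        assert max_flow(cg).value == 0.0

    def test_matches_augmenting_path_oracle_on_200_random_graphs(self, rng):
        for i in range(200):
            cg = random_capacity_graph(rng, int(rng.integers(4, 13)))
            got = max_flow(cg)
            want = edmonds_karp_oracle(cg.capacities, PSEUDO_SOURCE, PSEUDO_SINK)
            assert round(got.value * cg.scale) == want, f"instance {i}"

    def test_conservation_and_bounds_on_random_graphs(self, rng):
        for _ in range(50):
            cg = random_capacity_graph(rng, int(rng.integers(4, 13)))
            fr = max_flow(cg)
            assert fr.value <= min(len(cg.sources), len(cg.sinks)) + 1e-12
            net = {}
            for (u, v), f in fr.edge_flow.items():
                fi = round(f * cg.scale)
                net[u] = net.get(u, 0) - fi
                net[v] = net.get(v, 0) + fi
            for n, balance in net.items():
                if n in cg.sources:
                    assert balance <= 0 or balance == -0
                elif n in cg.sinks:
                    assert balance >= 0
                else:
                    assert balance == 0, f"conservation violated at {n}"

    def test_value_invariant_under_relabeling_and_zero_edges(self, rng):
        cg = random_capacity_graph(rng, 10)
        v0 = max_flow(cg).value
        ren = {n: f"x_{n}" for n in
               {x for e in cg.capacities for x in e
                if x not in (PSEUDO_SOURCE, PSEUDO_SINK)}}
        ren[PSEUDO_SOURCE] = PSEUDO_SOURCE
        ren[PSEUDO_SINK] = PSEUDO_SINK
        caps2 = {(ren[u], ren[v]): c for (u, v), c in cg.capacities.items()}
        caps2[("x_n1", "x_n0")] = caps2.get(("x_n1", "x_n0"), 0)
        cg2 = CapacityGraph({k: v for k, v in caps2.items()},
                            [ren[s] for s in cg.sources],
                            [ren[t] for t in cg.sinks])
        assert max_flow(cg2).value == pytest.approx(v0)


class TestFlowProfile:
    def test_specificity_of_simple_preference_vector(self):
        # direct check of the max-over-sum definition used throughout
        import pandas as pd
        from dimflow.flow import _specificity
        df = pd.DataFrame([[0.6, 0.2, 0.0]])
        assert _specificity(df).iloc[0] == pytest.approx(0.75)
        df2 = pd.DataFrame([[0.6, 0.2, 0.2]])
        assert _specificity(df2).iloc[0] == pytest.approx(0.6)

    def test_unique_route_gives_full_combined_specificity(self):
        g = annotated_graph([("s", "a", 9, 0), ("a", "m", 9, 0),
                             ("s2", "b", 9, 0), ("b", "m2", 9, 0)],
                            {"s": "olf", "s2": "vis"},
                            {"m": "leg", "m2": "wing"})
        prof = flow_profile(g, ["olf", "vis"], ["leg", "wing"])
        assert prof.combined_specificity["a"] == pytest.approx(1.0)
        assert prof.sensory_preference.loc["a"].idxmax() == "olf"

    def test_route_interneurons_prefer_their_modality(self):
        from dimflow.labels import DEFAULT_DOMAINS, DEFAULT_MODALITIES
        from dimflow.synth import (SensorimotorGenConfig,
                                   generate_sensorimotor_graph)
        hits = total = 0
        for seed in range(5):
            g, truth = generate_sensorimotor_graph(
                SensorimotorGenConfig(seed=seed))
            prof = flow_profile(g, list(DEFAULT_MODALITIES),
                                list(DEFAULT_DOMAINS))
            for n, (mod, dom) in truth.route_membership.items():
                total += 1
                hits += prof.sensory_preference.loc[n].idxmax() == mod
        assert hits / total >= 0.9

    def test_utilization_bounded(self, sensorimotor_default):
        g, _ = sensorimotor_default
        from dimflow.labels import DEFAULT_DOMAINS, DEFAULT_MODALITIES
        prof = flow_profile(g, list(DEFAULT_MODALITIES)[:2],
                            list(DEFAULT_DOMAINS)[:2])
        assert ((prof.utilization >= 0) & (prof.utilization <= 1)).all()


class TestPseudoLayers:
    def _layers(self, edge_flow, value=1.0):
        from dimflow.flow import FlowResult
        return pseudo_layers(FlowResult(("m", "d"), value, edge_flow, {}))

    def test_chain_gives_integer_hops(self):
        lv = self._layers({("s", "a"): 1.0, ("a", "b"): 1.0})
        assert lv.layers == pytest.approx({"s": 0.0, "a": 1.0, "b": 2.0})

    def test_weighted_two_input_example(self):
        # hand solve: layer(b) = 0.75*(1+1) + 0.25*(0+1) = 1.75
        lv = self._layers({("s", "a"): 0.75, ("a", "b"): 0.75,
                           ("s", "b"): 0.25})
        assert lv.layers["b"] == pytest.approx(1.75)

    def test_defining_equation_on_random_flow_dags(self, rng):
        from conftest import random_graph
        from dimflow.flow import max_flow as mf
        import test_flow as this
        checked = 0
        for i in range(100):
            cg = random_capacity_graph(rng, int(rng.integers(5, 12)))
            fr = mf(cg)
            if not fr.edge_flow:
                continue
            lv = pseudo_layers(fr)
            F = lv.flow_adjacency.to_numpy()
            nodes = list(lv.flow_adjacency.index)
            l = np.array([lv.layers[n] for n in nodes])
            has_in = F.sum(axis=0) > 0
            resid = ((l + 1) @ F - l)[has_in]
            assert np.max(np.abs(resid)) <= 1e-8, f"instance {i}"
            checked += 1
        assert checked >= 50

    def test_bfs_depth_when_single_input(self):
        lv = self._layers({("s", "a"): 0.4, ("a", "b"): 0.4, ("b", "c"): 0.4})
        assert lv.layers == pytest.approx({"s": 0, "a": 1, "b": 2, "c": 3})
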
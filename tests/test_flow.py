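"""Edmonds-Karp max flow against the exhaustive min-cut oracle and networkx."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppaflow import (
    CapacityScheme,
    Edge,
    FlowNetwork,
    SignalingNetwork,
    ValidationError,
    build_flow_network,
    flow_carrying_nodes,
    generate_flow_fixture,
    max_flow,
    min_cut_by_enumeration,
)


def nx_max_flow(flownet: FlowNetwork, s: str, t: str) -> int:
    """Independent reference value via networkx."""
    g = nx.DiGraph()
    g.add_nodes_from(flownet.nodes)
    for (u, v), c in flownet.capacities.items():
        g.add_edge(u, v, capacity=c)
    return nx.maximum_flow_value(g, s, t)


def random_flownet(seed: int) -> FlowNetwork:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    names = ["s"] + [f"n{i}" for i in range(1, n - 1)] + ["t"]
    caps = {}
    for u in names:
        for v in names:
            if u != v and rng.random() < 0.4:
                caps[(u, v)] = int(rng.integers(1, 10))
    return FlowNetwork(capacities=caps, nodes=set(names))


class TestBuildFlowNetwork:
    def test_undirected_interaction_expands_to_antiparallel_arcs(self):
        net = SignalingNetwork(edges=[Edge("A", "B", "interaction", directed=False)])
        fn = build_flow_network(net, CapacityScheme("s", 2, 5, 3))
        assert fn.capacities == {("A", "B"): 2, ("B", "A"): 2}

    def test_parallel_arcs_merge_by_capacity_sum(self):
        net = SignalingNetwork(
            edges=[Edge("A", "B", "direct"), Edge("A", "B", "indirect")]
        )
        fn = build_flow_network(net, CapacityScheme("s", 1, 3, 1))
        assert fn.capacities == {("A", "B"): 4}

    def test_zero_capacity_arcs_dropped(self):
        net = SignalingNetwork(edges=[Edge("A", "B", "direct")])
        fn = build_flow_network(net, CapacityScheme("s", 1, 0, 1))
        assert fn.capacities == {}
        assert "A" in fn.nodes  # molecules survive even if isolated

    def test_negative_capacity_rejected(self):
        with pytest.raises(ValidationError):
            CapacityScheme("s", -1, 1, 1)


class TestMaxFlow:
    def test_single_edge(self):
        fx = generate_flow_fixture("single-edge")
        res = max_flow(fx.flownet, "s", "t")
        assert res.value == fx.true_max_flow == 5
        assert res.min_cut_arcs == {("s", "t")}

    def test_disconnected(self):
        fx = generate_flow_fixture("disconnected")
        res = max_flow(fx.flownet, "s", "t")
        assert res.value == 0
        assert res.flow == {}

    def test_diamond(self):
        fx = generate_flow_fixture("diamond")
        res = max_flow(fx.flownet, "s", "t")
        assert res.value == fx.true_max_flow == 5
        assert res.min_cut_arcs == {("s", "a"), ("s", "b")}
        assert flow_carrying_nodes(res) == {"a", "b"}

    def test_missing_node_yields_zero_flow(self):
        fx = generate_flow_fixture("single-edge")
        assert max_flow(fx.flownet, "nowhere", "t").value == 0

    def test_source_equals_sink_rejected(self):
        fx = generate_flow_fixture("single-edge")
        with pytest.raises(ValidationError):
            max_flow(fx.flownet, "s", "s")

    @pytest.mark.parametrize("seed", range(500))
    def test_oracle_equivalence_on_random_graphs(self, seed):
        """Max-flow equals exhaustive min-cut enumeration on 500 random graphs."""
        fn = random_flownet(seed)
        assert max_flow(fn, "s", "t").value == min_cut_by_enumeration(fn, "s", "t")

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_networkx(self, seed):
        fn = random_flownet(seed + 1000)
        assert max_flow(fn, "s", "t").value == nx_max_flow(fn, "s", "t")

    @pytest.mark.parametrize("seed", range(30))
    def test_flow_invariants(self, seed):
        """Capacity bounds, conservation, integrality, cut value, path-bottleneck sum."""
        fn = random_flownet(seed)
        res = max_flow(fn, "s", "t")
        for (u, v), f in res.flow.items():
            assert isinstance(f, int)
            assert 0 <= f <= fn.capacities[(u, v)]
        net_out = {n: 0 for n in fn.nodes}
        for (u, v), f in res.flow.items():
            net_out[u] += f
            net_out[v] -= f
        for n in fn.nodes:
            if n not in ("s", "t"):
                assert net_out[n] == 0
        assert net_out["s"] == res.value
        assert net_out["t"] == -res.value
        assert sum(fn.capacities[a] for a in res.min_cut_arcs) == res.value
        assert sum(b for _, b in res.augmenting_paths) == res.value
        assert "s" in res.residual_reachable
        assert "t" not in res.residual_reachable

    @pytest.mark.parametrize("seed", range(20))
    def test_edmonds_karp_iteration_bound(self, seed):
        fn = random_flownet(seed)
        res = max_flow(fn, "s", "t")
        assert len(res.augmenting_paths) <= len(fn.nodes) * len(fn.capacities)

    @pytest.mark.parametrize("seed", range(20))
    def test_value_invariant_to_relabeling_and_arc_order(self, seed):
        fn = random_flownet(seed)
        ref = max_flow(fn, "s", "t").value
        relabel = {n: f"z{n}" for n in fn.nodes}
        relabel["s"], relabel["t"] = "s", "t"
        caps2 = {(relabel[u], relabel[v]): c for (u, v), c in fn.capacities.items()}
        shuffled = dict(reversed(list(caps2.items())))
        fn2 = FlowNetwork(capacities=shuffled, nodes=set(relabel.values()))
        assert max_flow(fn2, "s", "t").value == ref

    def test_antiparallel_expansion_does_not_double_capacity(self):
        """An undirected edge alone carries at most its single-direction capacity."""
        net = SignalingNetwork(edges=[Edge("s", "t", "interaction", directed=False)])
        fn = build_flow_network(net, CapacityScheme("u", 3, 3, 3))
        assert max_flow(fn, "s", "t").value == 3

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=60)
    def test_oracle_equivalence_property(self, seed):
        fn = random_flownet(seed)
        assert max_flow(fn, "s", "t").value == min_cut_by_enumeration(fn, "s", "t")

    def test_deterministic_augmenting_path_log(self):
        fn = random_flownet(7)
        r1, r2 = max_flow(fn, "s", "t"), max_flow(fn, "s", "t")
        assert r1.augmenting_paths == r2.augmenting_paths
        assert r1.flow == r2.flow


class TestFlowFixtures:
    @pytest.mark.parametrize("kind", ["single-edge", "disconnected", "diamond", "random-small"])
    def test_fixture_self_consistency(self, kind):
        fx = generate_flow_fixture(kind, seed=3)
        assert fx.true_max_flow == min_cut_by_enumeration(fx.flownet, fx.source, fx.sink)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            generate_flow_fixture("moebius")
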
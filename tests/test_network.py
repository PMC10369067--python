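"""Text-mining network: neighbor expansion, directed refinement, the
force-directed layout contract, and GPML export."""

import math

import pytest

from mapforge.diagram_io import parse_gpml
from mapforge.network import (
    DirectedEdge,
    LayoutParams,
    NetworkError,
    ScoredEdge,
    expand_neighbors,
    fr_layout,
    network_to_gpml,
    refine_directed,
)

EDGES = [
    ScoredEdge("A", "B", 900),
    ScoredEdge("A", "C", 850),
    ScoredEdge("A", "D", 700),
    ScoredEdge("B", "C", 400),
]


class TestExpandNeighbors:
    def test_best_score_first_truncation(self):
        nodes, edges = expand_neighbors(["A"], EDGES, min_score=800, max_new=1)
        assert nodes == ["A", "B"]
        assert [(e.a, e.b) for e in edges] == [("A", "B")]

    def test_max_new_zero_keeps_seed_subgraph(self):
        nodes, edges = expand_neighbors(["A", "B"], EDGES, min_score=0,
                                        max_new=0)
        assert nodes == ["A", "B"]
        assert {e.pair for e in edges} == {("A", "B")}

    def test_threshold_above_all_scores(self):
        nodes, edges = expand_neighbors(["A"], EDGES, min_score=1001,
                                        max_new=5)
        assert nodes == ["A"] and edges == []

    def test_empty_seed_set_warns(self):
        warnings = []
        nodes, edges = expand_neighbors([], EDGES, warnings=warnings)
        assert nodes == [] and edges == [] and warnings

    def test_tie_break_by_symbol(self):
        edges = [ScoredEdge("A", "Z", 900), ScoredEdge("A", "B", 900)]
        nodes, _ = expand_neighbors(["A"], edges, min_score=800, max_new=1)
        assert nodes == ["A", "B"]

    def test_monotone_in_max_new(self):
        prev = set()
        for m in range(4):
            nodes, _ = expand_neighbors(["A"], EDGES, min_score=0, max_new=m)
            assert prev <= set(nodes)
            prev = set(nodes)

    def test_antitone_in_min_score(self):
        prev_edges = None
        for score in (900, 800, 700, 400, 0):
            _, edges = expand_neighbors(["A", "B", "C", "D"], EDGES,
                                        min_score=score, max_new=0)
            pairs = {e.pair for e in edges}
            if prev_edges is not None:
                assert prev_edges <= pairs
            prev_edges = pairs

    def test_negative_min_score_rejected(self):
        with pytest.raises(NetworkError):
            expand_neighbors(["A"], EDGES, min_score=-1)


class TestRefineDirected:
    DIRECTED = [
        DirectedEdge("A", "B", "activation"),
        DirectedEdge("A", "X", "inhibition"),
    ]

    def test_membership_rule(self):
        out = refine_directed({"A", "B", "C"}, self.DIRECTED)
        assert [(e.source, e.target) for e in out] == [("A", "B")]

    def test_empty_table(self):
        assert refine_directed({"A"}, []) == []

    def test_all_present_identity_up_to_order(self):
        directed = [DirectedEdge("B", "A"), DirectedEdge("A", "B")]
        out = refine_directed({"A", "B"}, directed)
        assert [(e.source, e.target) for e in out] == [("A", "B"), ("B", "A")]

    def test_invariant_to_input_order(self):
        fwd = refine_directed({"A", "B", "X"}, self.DIRECTED)
        rev = refine_directed({"A", "B", "X"}, self.DIRECTED[::-1])
        assert fwd == rev

    def test_output_subset_of_input(self):
        out = refine_directed({"A", "B"}, self.DIRECTED)
        assert {(e.source, e.target, e.sign) for e in out} <= {
            (e.source, e.target, e.sign) for e in self.DIRECTED
        }


def two_body_oracle(k, t0=100.0, iters=300):
    """Independent two-particle force simulation: one edge, repulsion
    k^2/d, attraction d^2/k, linear cooling.  Returns the final distance."""
    x1, x2 = 100.0, 900.0
    for it in range(iters):
        t = t0 * (1 - it / iters)
        d = abs(x2 - x1)
        force = (k * k) / d - (d * d) / k  # net on particle 2, away from 1
        step = min(abs(force), t) * (1 if force > 0 else -1)
        x2 += step
        x1 -= step
    return abs(x2 - x1)


class TestFrLayout:
    def test_single_node_at_seeded_initial_position(self):
        import numpy as np

        params = LayoutParams(seed=5)
        pos = fr_layout(["A"], [], params)
        rng = np.random.default_rng(5)
        expected = (rng.uniform(0, params.width, 1)[0],
                    rng.uniform(0, params.height, 1)[0])
        assert pos["A"] == pytest.approx(expected)

    def test_two_nodes_settle_near_ideal_distance(self):
        params = LayoutParams(width=1000, height=1000, iterations=300,
                              initial_temperature=100, seed=3)
        pos = fr_layout(["A", "B"], [("A", "B")], params)
        k = math.sqrt(1000 * 1000 / 2)
        d = math.dist(pos["A"], pos["B"])
        assert abs(d - k) / k < 0.10
        # the independent oracle settles at the same equilibrium
        assert abs(two_body_oracle(k) - k) / k < 0.10

    def test_deterministic_under_seed(self):
        params = LayoutParams(seed=11, iterations=60)
        nodes = [f"n{i}" for i in range(12)]
        edges = [(f"n{i}", f"n{(i + 1) % 12}") for i in range(12)]
        assert fr_layout(nodes, edges, params) == fr_layout(nodes, edges,
                                                            params)

    def test_coordinates_clamped_to_area(self):
        params = LayoutParams(width=200, height=150, iterations=80, seed=2)
        pos = fr_layout([f"n{i}" for i in range(15)], [], params)
        for x, y in pos.values():
            assert 0 <= x <= 200 and 0 <= y <= 150

    def test_empty_graph(self):
        assert fr_layout([], [], LayoutParams()) == {}

    def test_invalid_iterations(self):
        with pytest.raises(NetworkError):
            LayoutParams(iterations=0)


class TestNetworkToGpml:
    POS = {"A": (100.0, 100.0), "B": (300.0, 200.0)}

    def test_emitted_element_counts(self):
        gpml = network_to_gpml(["A", "B"],
                               [DirectedEdge("A", "B", "activation")],
                               self.POS)
        assert gpml.count("<DataNode") == 2
        assert gpml.count("<Interaction") == 1
        assert 'ArrowHead="Arrow"' in gpml

    def test_inhibition_uses_tbar(self):
        gpml = network_to_gpml(["A", "B"],
                               [DirectedEdge("A", "B", "inhibition")],
                               self.POS)
        assert 'ArrowHead="TBar"' in gpml

    def test_empty_network_is_valid_pathway(self):
        d, report = parse_gpml(network_to_gpml([], [], {}))
        assert len(d.glyphs) == 0 and len(d.arcs) == 0

    def test_round_trip_preserves_labels_and_positions(self):
        gpml = network_to_gpml(["A", "B"],
                               [DirectedEdge("A", "B", "activation")],
                               self.POS)
        d, report = parse_gpml(gpml)
        assert report.dropped_arcs == 0
        centers = {g.label: (g.x + g.width / 2, g.y + g.height / 2)
                   for g in d.glyphs}
        assert centers["A"] == pytest.approx(self.POS["A"])
        assert centers["B"] == pytest.approx(self.POS["B"])

    def test_isolated_nodes_included(self):
        gpml = network_to_gpml(["A", "B", "LONE"], [], {**self.POS,
                                                        "LONE": (5.0, 5.0)})
        d, _ = parse_gpml(gpml)
        assert {g.label for g in d.glyphs} == {"A", "B", "LONE"}

    def test_missing_position_is_error(self):
        with pytest.raises(NetworkError, match="position"):
            network_to_gpml(["A", "B"], [], {"A": (0.0, 0.0)})
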
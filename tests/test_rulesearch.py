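"""Constraint-based rule enumeration and network search."""

import itertools

import pytest

from dzgrn import find_attractors
from dzgrn.network import BooleanNetwork, expr_from_table
from dzgrn.rulesearch import (
    AttractorConstraint,
    EdgeConstraint,
    SearchSpaceError,
    Topology,
    enumerate_functions,
    search_networks,
    topology_from_catalog,
)


class TestEnumerateFunctions:
    def test_one_mandatory_positive_is_identity(self):
        tables = enumerate_functions(("A",), [EdgeConstraint("A", "X", "MPU")])
        assert tables == [(0, 1)]  # of the four 1-input tables

    def test_one_mandatory_negative_is_negation(self):
        tables = enumerate_functions(("A",), [EdgeConstraint("A", "X", "MNU")])
        assert tables == [(1, 0)]

    def test_empty_regulator_set_gives_constants(self):
        assert enumerate_functions((), []) == [(0,), (1,)]

    def test_optional_regulators_unconstrained(self):
        tables = enumerate_functions(("A",), [EdgeConstraint("A", "X", "OPPA")])
        assert len(tables) == 4  # all 1-input tables admissible

    def test_two_mandatory_positive(self):
        tables = enumerate_functions(
            ("A", "B"),
            [EdgeConstraint("A", "X", "MPU"), EdgeConstraint("B", "X", "MPU")],
        )
        # monotone increasing + both essential: AND and OR only
        assert set(tables) == {(0, 0, 0, 1), (0, 1, 1, 1)}

    def test_guard_exceeded(self):
        regs = tuple("ABCDE")
        with pytest.raises(SearchSpaceError):
            enumerate_functions(regs, [])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            EdgeConstraint("A", "X", "XXX")


class TestSearchNetworks:
    def test_toggle_topology_yields_mutual_repression(self):
        topo = Topology(
            ("A", "B"),
            (EdgeConstraint("B", "A", "MNU"), EdgeConstraint("A", "B", "MNU")),
        )
        nets = search_networks(
            topo,
            AttractorConstraint(required=({"A": 1, "B": 0}, {"A": 0, "B": 1})),
        )
        assert len(nets) == 1
        assert nets[0].rules["A"].unparse() == "!B"
        assert nets[0].rules["B"].unparse() == "!A"

    def test_single_node_identity(self):
        topo = Topology(("A",), (EdgeConstraint("A", "A", "OPPA"),))
        nets = search_networks(
            topo, AttractorConstraint(required=({"A": 0}, {"A": 1}))
        )
        assert len(nets) == 1
        assert nets[0].rules["A"].unparse() == "A"

    def test_soundness_by_independent_attractor_check(self):
        topo = Topology(
            ("A", "B"),
            (
                EdgeConstraint("A", "A", "OPPA"),
                EdgeConstraint("B", "A", "ONPA"),
                EdgeConstraint("A", "B", "OPPA"),
            ),
        )
        constraints = AttractorConstraint(
            required=({"A": 1, "B": 1},), forbidden=({"A": 1, "B": 0},)
        )
        for net in search_networks(topo, constraints):
            fps = [
                dict(zip(net.nodes, net.decode(a.states[0])))
                for a in find_attractors(net).fixed_points
            ]
            assert any(s["A"] == 1 and s["B"] == 1 for s in fps)
            assert not any(s["A"] == 1 and s["B"] == 0 for s in fps)

    def test_completeness_against_brute_force_on_two_nodes(self):
        """On an unconstrained 2-node wiring the search equals a scan
        over every rule assignment."""
        topo = Topology(
            ("A", "B"),
            (
                EdgeConstraint("A", "A", "OPPA"),
                EdgeConstraint("B", "A", "OPPA"),
                EdgeConstraint("A", "B", "OPPA"),
                EdgeConstraint("B", "B", "OPPA"),
            ),
        )
        from dzgrn.logic import truth_table

        constraints = AttractorConstraint(required=({"A": 1, "B": 1},))
        found = {
            (
                tuple(truth_table(net.rules["A"], ("A", "B"))),
                tuple(truth_table(net.rules["B"], ("A", "B"))),
            )
            for net in search_networks(topo, constraints)
        }
        brute = set()
        for ta in itertools.product((0, 1), repeat=4):
            for tb in itertools.product((0, 1), repeat=4):
                net = BooleanNetwork(
                    ("A", "B"),
                    {
                        "A": expr_from_table(("A", "B"), list(ta)),
                        "B": expr_from_table(("A", "B"), list(tb)),
                    },
                )
                fps = [
                    net.decode(a.states[0])
                    for a in find_attractors(net).fixed_points
                ]
                if (1, 1) in fps:
                    brute.add((ta, tb))
        assert found == brute

    def test_emptiness_is_reported_not_raised(self):
        topo = Topology(("A",), (EdgeConstraint("A", "A", "MPU"),))
        # identity rule has fixed points {0} and {1}; forbidding both
        # leaves nothing
        nets = search_networks(
            topo,
            AttractorConstraint(
                required=(), forbidden=({"A": 0}, {"A": 1})
            ),
        )
        assert nets == []


def test_initial_dz_topology_is_unsatisfiable(catalog):
    """No rule assignment on the experimentally supported wiring alone
    yields the four required cell-type fixed points: the LL and SL
    profiles address the same ALC truth-table entry with opposite
    outputs, so candidate pruning empties at ALC."""
    topo = topology_from_catalog(catalog, "initial")
    nodes = set(catalog.initial_network.nodes)
    required = tuple(
        {k: v for k, v in catalog.profile(n).marker_states.items() if k in nodes}
        for n in ("V", "LL", "SL", "R")
    )
    assert search_networks(topo, AttractorConstraint(required=required)) == []
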
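"""Constraint-based enumeration of Boolean rules on a signed topology.

A desk-scale analogue of exhaustive logical-rule inference: every edge
of a topology carries a constraint class,

* ``MPU`` / ``MNU`` — mandatory positive / negative, unambiguous: the
  regulator must be essential (the output depends on it) and the
  function must be monotone increasing / decreasing in it;
* ``OPPA`` / ``ONPA`` — optional positive / negative, possibly
  ambiguous: the regulator may be dropped and its sign is left free.

Per-node candidate functions are enumerated over all truth tables of
the node's regulator set (guarded at four regulators, 2^16 tables) and
a network-level search returns every assignment whose synchronous fixed
points include all required states and exclude all forbidden ones.
Emptiness is a valid, reported outcome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .attractors import find_attractors
from .network import BooleanNetwork, expr_from_table
from .logic import Expr

MAX_REGULATORS = 4
MAX_ASSIGNMENTS = 2_000_000

MANDATORY = {"MPU": +1, "MNU": -1}
OPTIONAL = {"OPPA", "ONPA"}


class SearchSpaceError(ValueError):
    """Enumeration guard exceeded; carries the offending node."""


@dataclass(frozen=True)
class EdgeConstraint:
    regulator: str
    target: str
    klass: str  # MPU | MNU | OPPA | ONPA

    def __post_init__(self):
        if self.klass not in MANDATORY and self.klass not in OPTIONAL:
            raise ValueError(f"unknown constraint class {self.klass!r}")


@dataclass(frozen=True)
class AttractorConstraint:
    """Required / forbidden fixed points as (possibly partial) states.

    States are dicts node -> {0,1}; nodes absent from a partial state
    are unconstrained.
    """

    required: tuple[dict[str, int], ...] = ()
    forbidden: tuple[dict[str, int], ...] = ()


def _essential(table: list[int], pos: int, m: int) -> bool:
    for k in range(1 << m):
        if not (k >> pos) & 1 and table[k] != table[k | (1 << pos)]:
            return True
    return False


def _monotone(table: list[int], pos: int, m: int, sign: int) -> bool:
    for k in range(1 << m):
        if not (k >> pos) & 1:
            lo, hi = table[k], table[k | (1 << pos)]
            if sign > 0 and lo > hi:
                return False
            if sign < 0 and lo < hi:
                return False
    return True


def enumerate_functions(
    regulators: tuple[str, ...], constraints: list[EdgeConstraint]
) -> list[tuple[int, ...]]:
    """All admissible truth tables over ``regulators``.

    Returns deduplicated tables (tuples of output bits indexed by the
    regulator assignment, regulator ``i`` at bit ``i``).  With an empty
    regulator set the two constants are returned.
    """
    m = len(regulators)
    if m > MAX_REGULATORS:
        raise SearchSpaceError(
            f"{m} regulators exceeds the exhaustive guard of {MAX_REGULATORS}"
        )
    classes = {c.regulator: c.klass for c in constraints}
    unknown = set(classes) - set(regulators)
    if unknown:
        raise ValueError(f"constraints on non-regulators: {sorted(unknown)}")
    out = []
    for bits in range(1 << (1 << m)):
        table = [(bits >> k) & 1 for k in range(1 << m)]
        ok = True
        for pos, reg in enumerate(regulators):
            klass = classes.get(reg)
            if klass in MANDATORY:
                if not _essential(table, pos, m) or not _monotone(
                    table, pos, m, MANDATORY[klass]
                ):
                    ok = False
                    break
        if ok:
            out.append(tuple(table))
    return out


@dataclass(frozen=True)
class Topology:
    """Node list plus constrained edges; regulator order per node is the
    edge-listing order."""

    nodes: tuple[str, ...]
    edges: tuple[EdgeConstraint, ...]

    def regulators_of(self, node: str) -> tuple[str, ...]:
        return tuple(e.regulator for e in self.edges if e.target == node)

    def constraints_of(self, node: str) -> list[EdgeConstraint]:
        return [e for e in self.edges if e.target == node]


def _state_key(state: dict[str, int], nodes: tuple[str, ...]) -> int | None:
    """Integer encoding of a complete state, or None if partial."""
    if any(n not in state for n in nodes):
        return None
    code = 0
    for i, n in enumerate(nodes):
        code |= int(state[n]) << i
    return code


def search_networks(
    topology: Topology,
    constraints: AttractorConstraint,
    limit: int | None = None,
) -> list[BooleanNetwork]:
    """Every rule assignment consistent with the topology and the
    fixed-point constraints (possibly none).

    Candidates are pruned per node first: a required state that fixes a
    node's regulators and its own value rules out every table with the
    wrong output, which typically collapses the search space by orders
    of magnitude before the cross product is enumerated.
    """
    per_node: dict[str, list[tuple[int, ...]]] = {}
    reg_sets: dict[str, tuple[str, ...]] = {}
    for node in topology.nodes:
        regs = topology.regulators_of(node)
        reg_sets[node] = regs
        try:
            cands = enumerate_functions(regs, topology.constraints_of(node))
        except SearchSpaceError as err:
            raise SearchSpaceError(f"node {node}: {err}") from err
        # prune on required fixed points
        for state in constraints.required:
            if node not in state or any(r not in state for r in regs):
                continue
            key = 0
            for i, r in enumerate(regs):
                key |= int(state[r]) << i
            want = int(state[node])
            cands = [t for t in cands if t[key] == want]
        per_node[node] = cands
        if not cands:
            return []

    space = 1
    for cands in per_node.values():
        space *= len(cands)
    bound = limit or MAX_ASSIGNMENTS
    if space > bound:
        worst = max(per_node, key=lambda n: len(per_node[n]))
        raise SearchSpaceError(
            f"{space} rule assignments exceed the bound {bound} "
            f"(largest candidate list at node {worst})"
        )

    results = []
    names = list(topology.nodes)
    for combo in itertools.product(*(per_node[n] for n in names)):
        net = BooleanNetwork(
            tuple(names),
            {
                n: expr_from_table(reg_sets[n], list(t))
                for n, t in zip(names, combo)
            },
        )
        if _satisfies(net, constraints):
            results.append(net)
    return results


def topology_from_catalog(catalog, which: str = "initial") -> Topology:
    """Constrained topology from the interaction catalogue.

    Well-supported transcriptional edges become mandatory (MPU/MNU by
    sign), suggested edges optional (OPPA/ONPA); protein--protein rows
    and edges touching nodes outside the chosen network (the folded
    ARF6/8 group) are skipped.
    """
    net = (
        catalog.initial_network if which == "initial" else catalog.final_network
    )
    nodes = set(net.nodes)
    edges = []
    for r in catalog.interactions:
        if which == "initial" and not r.in_initial_model:
            continue
        if r.evidence == "ppi" or r.sign is None:
            continue
        if r.regulator not in nodes or r.target not in nodes:
            continue
        if r.evidence == "well_supported" or r.in_initial_model:
            klass = "MPU" if r.sign == "activation" else "MNU"
        else:
            klass = "OPPA" if r.sign == "activation" else "ONPA"
        edges.append(EdgeConstraint(r.regulator, r.target, klass))
    return Topology(nodes=net.nodes, edges=tuple(edges))


def _satisfies(net: BooleanNetwork, constraints: AttractorConstraint) -> bool:
    fps = [
        net.decode(a.states[0])
        for a in find_attractors(net).fixed_points
    ]
    states = [dict(zip(net.nodes, fp)) for fp in fps]

    def match(req: dict[str, int], st: dict[str, int]) -> bool:
        return all(st.get(k) == v for k, v in req.items() if k in st)

    for req in constraints.required:
        if not any(match(req, st) for st in states):
            return False
    for bad in constraints.forbidden:
        if any(match(bad, st) for st in states):
            return False
    return True
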
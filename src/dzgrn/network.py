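"""Synchronous Boolean networks: representation, parsing, and dynamics.

A :class:`BooleanNetwork` holds an ordered node list and one rule per
node.  The node order is fixed and defines the state encoding: node
``i`` occupies bit ``i`` of the unsigned-integer encoding of a state
(least significant bit = node 0).  All nodes update simultaneously:

    x_i(t+1) = f_i(x_{i1}(t), ..., x_{im}(t))

Clamped nodes ignore their rule and hold a constant value, which is how
loss- and gain-of-function mutants are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .logic import Const, Expr, RuleSyntaxError, parse_expression, truth_table

#: exhaustive state-space enumeration guard
MAX_NODES = 24

HEADER = "targets, factors"


class NetworkSizeError(ValueError):
    """State space too large for exhaustive enumeration."""


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered set of nodes with one Boolean rule each.

    Parameters
    ----------
    nodes
        Unique node names; the order defines bit positions.
    rules
        Mapping node -> rule expression; every free identifier of every
        rule must itself be a node.
    clamps
        Optional partial mapping node -> {0, 1}.  A clamped node keeps
        the clamp value regardless of its rule.
    """

    nodes: tuple[str, ...]
    rules: Mapping[str, Expr]
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        if set(self.rules) != set(self.nodes):
            missing = set(self.nodes) ^ set(self.rules)
            raise ValueError(f"rules/nodes mismatch: {sorted(missing)}")
        known = set(self.nodes)
        for name, rule in self.rules.items():
            unknown = set(rule.variables()) - known
            if unknown:
                raise ValueError(
                    f"rule for {name} references unknown node(s) {sorted(unknown)}"
                )
        for name, value in self.clamps.items():
            if name not in known:
                raise ValueError(f"clamped node {name!r} is not in the network")
            if value not in (0, 1):
                raise ValueError(f"clamp value for {name} must be 0 or 1")

    # -- basic properties --------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def regulators(self, node: str) -> tuple[str, ...]:
        """Free identifiers of the node's rule (its regulator set)."""
        return self.rules[node].variables()

    def with_clamps(self, clamps: Mapping[str, int]) -> "BooleanNetwork":
        merged = {**self.clamps, **clamps}
        return replace(self, clamps=merged)

    # -- state encoding ----------------------------------------------------

    def encode(self, state: Sequence[int]) -> int:
        if len(state) != self.n:
            raise ValueError(f"state length {len(state)} != {self.n} nodes")
        code = 0
        for i, bit in enumerate(state):
            if bit not in (0, 1):
                raise ValueError("state entries must be 0 or 1")
            code |= bit << i
        return code

    def decode(self, code: int) -> tuple[int, ...]:
        return tuple((code >> i) & 1 for i in range(self.n))

    def state_from_dict(self, values: Mapping[str, int]) -> tuple[int, ...]:
        return tuple(int(values[name]) for name in self.nodes)

    # -- dynamics ----------------------------------------------------------

    def step(self, state: Sequence[int]) -> tuple[int, ...]:
        """One synchronous update of every node."""
        if len(state) != self.n:
            raise ValueError(f"state length {len(state)} != {self.n} nodes")
        env = dict(zip(self.nodes, state))
        nxt = []
        for name in self.nodes:
            if name in self.clamps:
                nxt.append(self.clamps[name])
            else:
                nxt.append(self.rules[name].evaluate(env))
        return tuple(nxt)

    def node_tables(self) -> dict[str, tuple[tuple[int, ...], list[int]]]:
        """Per-node (regulator indices, truth-table column).

        The truth table of a clamped node is the constant clamp value
        with an empty regulator set.
        """
        out: dict[str, tuple[tuple[int, ...], list[int]]] = {}
        for name in self.nodes:
            if name in self.clamps:
                out[name] = ((), [self.clamps[name]])
                continue
            regs = self.regulators(name)
            out[name] = (
                tuple(self.index(r) for r in regs),
                truth_table(self.rules[name], regs),
            )
        return out

    def successor_array(self) -> np.ndarray:
        """Vector of integer-encoded successors for all 2^n states."""
        if self.n > MAX_NODES:
            raise NetworkSizeError(
                f"{self.n} nodes exceeds the exhaustive guard of {MAX_NODES}"
            )
        states = np.arange(1 << self.n, dtype=np.int64)
        succ = np.zeros_like(states)
        for name, (reg_idx, table) in self.node_tables().items():
            key = np.zeros_like(states)
            for pos, idx in enumerate(reg_idx):
                key |= ((states >> idx) & 1) << pos
            bits = np.asarray(table, dtype=np.int64)[key]
            succ |= bits << self.index(name)
        return succ

    def truth_table_hash(self) -> str:
        """Hash of all per-node truth tables; ties outputs to the exact
        rule transcription regardless of expression syntax."""
        import hashlib

        h = hashlib.sha256()
        for name in self.nodes:
            reg_idx, table = self.node_tables()[name]
            h.update(name.encode())
            h.update(bytes(reg_idx))
            h.update(bytes(table))
        return h.hexdigest()[:16]


# --- rule-file dialect ------------------------------------------------------


def parse_rules(text: str) -> BooleanNetwork:
    """Parse BoolNet-style rule text into a network.

    The first non-blank line must be exactly ``targets, factors``; each
    following line is ``NODE, <expression>``.  Lines starting with ``#``
    are comments.
    """
    lines = text.splitlines()
    nodes: list[str] = []
    rules: dict[str, Expr] = {}
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if line != HEADER:
                raise RuleSyntaxError(
                    f"expected header {HEADER!r}, got {line!r}", lineno
                )
            header_seen = True
            continue
        if "," not in line:
            raise RuleSyntaxError("expected 'NODE, expression'", lineno)
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not target:
            raise RuleSyntaxError("empty target name", lineno)
        if target in rules:
            raise RuleSyntaxError(f"duplicate target {target!r}", lineno)
        nodes.append(target)
        rules[target] = parse_expression(expr_text, lineno)
    if not header_seen:
        raise RuleSyntaxError(f"missing header {HEADER!r}")
    if not nodes:
        raise RuleSyntaxError("no rules found")
    net = BooleanNetwork(tuple(nodes), rules)
    return net


def write_rules(net: BooleanNetwork) -> str:
    """Serialize a network in the rule-file dialect (round-trips).

    Clamped nodes are written as the constant ``0``/``1`` so that GOF and
    LOF networks serialize faithfully.
    """
    out = [HEADER]
    for name in net.nodes:
        if name in net.clamps:
            expr: Expr = Const(net.clamps[name])
        else:
            expr = net.rules[name]
        out.append(f"{name}, {expr.unparse()}")
    return "\n".join(out) + "\n"


def network_from_tables(
    nodes: Sequence[str],
    tables: Mapping[str, tuple[Sequence[str], Sequence[int]]],
) -> BooleanNetwork:
    """Build a network from explicit per-node truth tables.

    Each table column is converted back to a (canonical DNF) expression
    so the result behaves like any parsed network, including
    serialization.  Used by the random-ensemble generator and the rule
    search.
    """
    rules: dict[str, Expr] = {}
    for name in nodes:
        regs, column = tables[name]
        rules[name] = expr_from_table(regs, column)
    return BooleanNetwork(tuple(nodes), rules)


def expr_from_table(regs: Sequence[str], column: Sequence[int]) -> Expr:
    """Canonical sum-of-minterms expression for a truth-table column."""
    if len(column) != 1 << len(regs):
        raise ValueError("truth-table length does not match regulator count")
    from .logic import And, Not, Or, Var

    # constant columns still reference every regulator so that the
    # regulator set (and hence the wiring) survives table edits
    if all(v == 0 for v in column):
        if not regs:
            return Const(0)
        expr: Expr = And(Var(regs[0]), Not(Var(regs[0])))
        for r in regs[1:]:
            expr = Or(expr, And(Var(r), Not(Var(r))))
        return expr
    if all(v == 1 for v in column):
        if not regs:
            return Const(1)
        expr = Or(Var(regs[0]), Not(Var(regs[0])))
        for r in regs[1:]:
            expr = And(expr, Or(Var(r), Not(Var(r))))
        return expr

    terms: list[Expr] = []
    for k, v in enumerate(column):
        if not v:
            continue
        lits: list[Expr] = []
        for i, r in enumerate(regs):
            lit: Expr = Var(r)
            if not (k >> i) & 1:
                lit = Not(lit)
            lits.append(lit)
        term = lits[0]
        for lit in lits[1:]:
            term = And(term, lit)
        terms.append(term)
    expr = terms[0]
    for term in terms[1:]:
        expr = Or(expr, term)
    return expr
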
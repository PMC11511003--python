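"""Exhaustive attractor enumeration for synchronous Boolean networks.

Synchronous dynamics on ``2^n`` states form a functional graph (every
state has exactly one successor), so every trajectory ends in a unique
cycle.  Attractors are found by pointer doubling on the successor
array: composing the successor map with itself ``ceil(log2(2^n))``
times sends every state onto its attractor cycle, after which cycles
are traced directly and basin sizes counted.  Each state is touched
O(log 2^n) times in vectorized form, exact and fast up to the
``MAX_NODES`` guard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import BooleanNetwork


@dataclass(frozen=True)
class TransitionTable:
    """Total synchronous successor map over all ``2^n`` states."""

    nodes: tuple[str, ...]
    successor: np.ndarray  # shape (2^n,), integer-encoded successors

    def __post_init__(self):
        if len(self.successor) != 1 << len(self.nodes):
            raise ValueError("successor array length must be 2^n")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def __getitem__(self, state: int) -> int:
        return int(self.successor[state])


def build_transition_table(net: BooleanNetwork) -> TransitionTable:
    """Tabulate ``step`` for every state (guarded at ``MAX_NODES``)."""
    return TransitionTable(nodes=net.nodes, successor=net.successor_array())


@dataclass(frozen=True)
class Attractor:
    """A terminal cycle of the synchronous dynamics.

    ``states`` is the ordered cycle of integer-encoded states, rotated
    so the smallest state comes first; length 1 means a fixed point.
    """

    states: tuple[int, ...]
    basin_size: int

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1


@dataclass(frozen=True)
class AttractorSet:
    """All attractors of a network, with the node order they refer to."""

    nodes: tuple[str, ...]
    attractors: tuple[Attractor, ...]

    def __iter__(self):
        return iter(self.attractors)

    def __len__(self):
        return len(self.attractors)

    @property
    def fixed_points(self) -> tuple[Attractor, ...]:
        return tuple(a for a in self.attractors if a.is_fixed_point)

    @property
    def cycles(self) -> tuple[Attractor, ...]:
        return tuple(a for a in self.attractors if not a.is_fixed_point)

    def decode(self, code: int) -> tuple[int, ...]:
        return tuple((code >> i) & 1 for i in range(len(self.nodes)))

    def state_dict(self, code: int) -> dict[str, int]:
        return dict(zip(self.nodes, self.decode(code)))


def _canonical_cycle(cycle: Sequence[int]) -> tuple[int, ...]:
    k = int(np.argmin(cycle))
    return tuple(cycle[k:]) + tuple(cycle[:k])


def attractors_from_successors(
    succ: np.ndarray, nodes: Sequence[str]
) -> AttractorSet:
    """Enumerate attractors and basins from a successor array."""
    n_states = len(succ)
    # pointer doubling: after k squarings, reach = succ^(2^k)
    reach = succ
    steps = max(1, int(np.ceil(np.log2(max(n_states, 2)))))
    for _ in range(steps):
        reach = reach[reach]
    on_cycle = np.unique(reach)

    label = np.full(n_states, -1, dtype=np.int64)
    cycles: list[tuple[int, ...]] = []
    for s in on_cycle:
        s = int(s)
        if label[s] != -1:
            continue
        cyc = [s]
        t = int(succ[s])
        while t != s:
            cyc.append(t)
            t = int(succ[t])
        for u in cyc:
            label[u] = len(cycles)
        cycles.append(_canonical_cycle(cyc))

    basin_label = label[reach]
    counts = np.bincount(basin_label, minlength=len(cycles))
    attrs = [
        Attractor(states=cyc, basin_size=int(counts[i]))
        for i, cyc in enumerate(cycles)
    ]
    attrs.sort(key=lambda a: a.states[0])
    return AttractorSet(nodes=tuple(nodes), attractors=tuple(attrs))


def find_attractors(net: BooleanNetwork) -> AttractorSet:
    """All attractors (fixed points and cycles) with exact basin sizes.

    Basin sizes sum to ``2^n``; every state of the space belongs to
    exactly one basin.
    """
    return attractors_from_successors(net.successor_array(), net.nodes)


def cycle_preserved(cycle: Sequence[int], succ: np.ndarray) -> bool:
    """True if the cycle is still an attractor under ``succ``.

    A state cycle of one network is an attractor of another network on
    the same node set iff the other network's successor map agrees on
    every cycle state (a closed orbit of a deterministic map is always
    terminal).
    """
    m = len(cycle)
    return all(int(succ[cycle[k]]) == cycle[(k + 1) % m] for k in range(m))
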
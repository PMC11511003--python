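"""Shared fixtures and the brute-force dynamics oracle.

The oracle deliberately avoids the package's traversal machinery: it
iterates ``step`` from every start state until a state repeats, so the
fast pointer-doubling enumeration can be checked against it on every
small network.
"""

from __future__ import annotations

import pytest

from dzgrn import find_attractors, load_catalog, parse_rules
from dzgrn.network import BooleanNetwork


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def final_net(catalog):
    return catalog.final_network


@pytest.fixture(scope="session")
def initial_net(catalog):
    return catalog.initial_network


@pytest.fixture(scope="session")
def cell_profiles(catalog):
    return [p for p in catalog.profiles if p.name != "VM"]


@pytest.fixture(scope="session")
def final_attractors(final_net):
    return find_attractors(final_net)


@pytest.fixture
def toggle():
    return parse_rules("targets, factors\nA, !B\nB, !A\n")


@pytest.fixture
def identity_net():
    return parse_rules("targets, factors\nA, A\n")


@pytest.fixture
def negation_net():
    return parse_rules("targets, factors\nA, !A\n")


def brute_force_attractors(net: BooleanNetwork):
    """Map of canonical cycle -> basin size, by explicit iteration."""
    assert net.n <= 8, "oracle is for small networks only"
    basins: dict[tuple[int, ...], int] = {}
    for start in range(1 << net.n):
        seen: dict[int, int] = {}
        s = start
        while s not in seen:
            seen[s] = len(seen)
            s = net.encode(net.step(net.decode(s)))
        cycle = [c for c, order in seen.items() if order >= seen[s]]
        k = cycle.index(min(cycle))
        canon = tuple(cycle[k:] + cycle[:k])
        basins[canon] = basins.get(canon, 0) + 1
    return basins
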
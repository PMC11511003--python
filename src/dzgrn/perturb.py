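"""In-silico mutant simulation by node clamping.

Constitutive loss-of-function (LOF) mutants clamp a node to 0 and
gain-of-function (GOF) mutants clamp it to 1; the clamped node's rule
is discarded and every attractor of the clamped network is classified
against the reference cell-type profiles.  Classification is an exact
match on all marker nodes, including clamped ones: a lignification
layer without IND activity, say, is reported as a novel configuration,
not as LL.
"""

from __future__ import annotations

from dataclasses import dataclass

from .attractors import AttractorSet, find_attractors
from .grn import CellTypeProfile, ModelCatalog, classify_state
from .network import BooleanNetwork


@dataclass(frozen=True)
class PerturbationSpec:
    """A constitutive mutant: clamp maps node -> 0 (LOF) or 1 (GOF)."""

    clamp: dict[str, int]
    label: str

    def __post_init__(self):
        if not self.clamp:
            raise ValueError("perturbation requires at least one clamped node")

    @classmethod
    def lof(cls, *nodes: str) -> "PerturbationSpec":
        return cls({n: 0 for n in nodes}, " ".join(nodes).lower() + " LOF")

    @classmethod
    def gof(cls, *nodes: str) -> "PerturbationSpec":
        return cls({n: 1 for n in nodes}, " ".join(nodes).upper() + " GOF")


@dataclass(frozen=True)
class MutantResult:
    spec: PerturbationSpec
    attractors: AttractorSet
    classification: tuple[tuple[int, str], ...]  # (fixed-point state, label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, label in self.classification)

    @property
    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.labels:
            counts[label] = counts.get(label, 0) + 1
        return counts


def apply_perturbation(
    net: BooleanNetwork, spec: PerturbationSpec
) -> BooleanNetwork:
    """Clamp the mutant's nodes; all other rules are unchanged."""
    unknown = set(spec.clamp) - set(net.nodes)
    if unknown:
        raise ValueError(f"unknown node(s) in perturbation: {sorted(unknown)}")
    return net.with_clamps(spec.clamp)


def simulate_mutant(
    net: BooleanNetwork,
    spec: PerturbationSpec,
    profiles: list[CellTypeProfile],
) -> MutantResult:
    """Attractors of the clamped network, classified per fixed point."""
    mutant = apply_perturbation(net, spec)
    aset = find_attractors(mutant)
    classification = tuple(
        (a.states[0], classify_state(aset.state_dict(a.states[0]), profiles))
        for a in aset.fixed_points
    )
    return MutantResult(spec=spec, attractors=aset, classification=classification)


#: the published mutant panel, in figure order (a-i)
PANEL = (
    PerturbationSpec.lof("FUL"),
    PerturbationSpec.gof("FUL"),
    PerturbationSpec.lof("SHP"),
    PerturbationSpec.gof("SHP"),
    PerturbationSpec.gof("NTT"),
    PerturbationSpec.lof("IND"),
    PerturbationSpec.lof("ALC"),
    PerturbationSpec.lof("SPT"),
    PerturbationSpec.lof("RPL"),
)


def mutant_panel(catalog: ModelCatalog) -> list[MutantResult]:
    """Run the nine-mutant LOF/GOF panel on the final network."""
    profiles = [p for p in catalog.profiles if p.name != "VM"]
    return [
        simulate_mutant(catalog.final_network, spec, profiles)
        for spec in PANEL
    ]
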
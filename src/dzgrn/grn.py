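"""The Arabidopsis dehiscence-zone GRN models and cell-type profiles.

The package ships two rule files and two CSV tables:

* ``initial.bnet`` — the 11-node network compiled from experimentally
  validated interactions only.  Its synchronous dynamics cannot separate
  the lignification layer (LL) from the separation layer (SL): both
  collapse into a single merged valve-margin attractor.
* ``final.bnet`` — the 12-node network that adds the NTT transcription
  factor and a small set of hypothetical interactions; it recovers one
  fixed point per cell type (valve V, lignification layer LL,
  separation layer SL, replum R).
* ``interactions.csv`` — the signed interaction catalogue with evidence
  classes (well supported / suggested / protein--protein) and a flag for
  membership in the initial model.
* ``profiles.csv`` — marker expression (0/1, blank = unspecified) of
  each node in the reference cell types, used to classify attractors.

The rule files are a reconstruction: the original publication did not
deposit a machine-readable rule listing, so the rules were rebuilt from
the interaction catalogue plus the reported wild-type and mutant
attractors, and every non-catalogue term is documented in
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .attractors import AttractorSet, find_attractors
from .network import BooleanNetwork, parse_rules

#: number of nodes of the compiled initial model
N_INITIAL_NODES = 11
#: number of experimentally validated interactions in the initial model
N_INITIAL_INTERACTIONS = 22


class CatalogValidationError(ValueError):
    """The shipped data files disagree with the documented counts."""


@dataclass(frozen=True)
class InteractionRecord:
    """One signed edge of the interaction catalogue."""

    regulator: str
    target: str
    sign: str | None  # "activation" | "repression" | None for PPIs
    evidence: str  # "well_supported" | "suggested" | "ppi"
    in_initial_model: bool
    reference: str


@dataclass(frozen=True)
class CellTypeProfile:
    """A reference expression state for one fruit cell type.

    ``marker_states`` is partial: only nodes whose tissue activity is
    established are constrained; all other nodes are free.
    """

    name: str
    marker_states: dict[str, int]

    def matches(self, state: dict[str, int]) -> bool:
        """Exact match on every marker node present in ``state``."""
        return all(
            state[node] == value
            for node, value in self.marker_states.items()
            if node in state
        )


@dataclass(frozen=True)
class ModelCatalog:
    initial_network: BooleanNetwork
    final_network: BooleanNetwork
    interactions: tuple[InteractionRecord, ...]
    profiles: tuple[CellTypeProfile, ...]

    def profile(self, name: str) -> CellTypeProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dzgrn").joinpath("data", name)))


def _read_interactions(path: Path) -> tuple[InteractionRecord, ...]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            InteractionRecord(
                regulator=row.regulator,
                target=row.target,
                sign=row.sign or None,
                evidence=row.evidence,
                in_initial_model=row.in_initial_model.lower() == "true",
                reference=row.reference,
            )
        )
    return tuple(records)


def _read_profiles(path: Path) -> tuple[CellTypeProfile, ...]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False).set_index("node")
    profiles = []
    for name in df.columns:
        markers = {
            node: int(v) for node, v in df[name].items() if v.strip() != ""
        }
        profiles.append(CellTypeProfile(name=name, marker_states=markers))
    return tuple(profiles)


def load_catalog(rules_dir: str | Path | None = None) -> ModelCatalog:
    """Load and validate the two DZ networks, catalogue and profiles.

    Parameters
    ----------
    rules_dir
        Directory containing ``initial.bnet``, ``final.bnet``,
        ``interactions.csv`` and ``profiles.csv``; defaults to the
        package's shipped data.
    """
    if rules_dir is None:
        paths = {n: _data_path(n) for n in (
            "initial.bnet", "final.bnet", "interactions.csv", "profiles.csv")}
    else:
        rules_dir = Path(rules_dir)
        paths = {n: rules_dir / n for n in (
            "initial.bnet", "final.bnet", "interactions.csv", "profiles.csv")}
    for p in paths.values():
        if not p.exists():
            raise FileNotFoundError(p)

    initial = parse_rules(paths["initial.bnet"].read_text())
    final = parse_rules(paths["final.bnet"].read_text())
    interactions = _read_interactions(paths["interactions.csv"])
    profiles = _read_profiles(paths["profiles.csv"])
    catalog = ModelCatalog(initial, final, interactions, profiles)
    _validate(catalog)
    return catalog


def _validate(catalog: ModelCatalog) -> None:
    initial, final = catalog.initial_network, catalog.final_network
    if initial.n != N_INITIAL_NODES:
        raise CatalogValidationError(
            f"initial model has {initial.n} nodes, expected {N_INITIAL_NODES}"
        )
    if set(final.nodes) != set(initial.nodes) | {"NTT"}:
        raise CatalogValidationError(
            "final node set must be the initial node set plus NTT"
        )
    initial_records = [
        r for r in catalog.interactions
        if r.in_initial_model and r.evidence in ("well_supported", "suggested")
    ]
    if len(initial_records) != N_INITIAL_INTERACTIONS:
        raise CatalogValidationError(
            f"{len(initial_records)} initial-model interactions catalogued, "
            f"expected {N_INITIAL_INTERACTIONS}: "
            + "; ".join(f"{r.regulator}->{r.target}" for r in initial_records)
        )
    # every catalogued name resolves to a network node (or the folded
    # ARF6/8 group, which appears only inside the MIR172 rule)
    known = set(final.nodes) | {"ARF68"}
    for r in catalog.interactions:
        for name in (r.regulator, r.target):
            if name not in known:
                raise CatalogValidationError(
                    f"catalogue references unknown node {name!r}"
                )


def reference_profiles() -> list[CellTypeProfile]:
    """The four final cell-type profiles (V, LL, SL, R) plus the merged
    valve-margin profile (VM) used by the initial model."""
    return list(_read_profiles(_data_path("profiles.csv")))


def classify_state(
    state: dict[str, int], profiles: list[CellTypeProfile] | None = None
) -> str:
    """Label a state with the unique matching profile, or ``novel``.

    Matching is exact on every marker node present in the state; a state
    matching zero profiles or more than one is ``novel`` (final profiles
    are pairwise distinguishable on markers, so multi-matches only arise
    for networks lacking the distinguishing nodes).
    """
    if profiles is None:
        profiles = [p for p in reference_profiles() if p.name != "VM"]
    hits = [p.name for p in profiles if p.matches(state)]
    return hits[0] if len(hits) == 1 else "novel"


@dataclass(frozen=True)
class WildtypeReport:
    """Mapping of a network's fixed points to cell-type profiles."""

    attractors: AttractorSet
    assignments: tuple[tuple[int, str], ...]  # (fixed-point state, label)
    matched: dict[str, int] = field(default_factory=dict)
    unmatched_profiles: tuple[str, ...] = ()

    @property
    def separates_ll_sl(self) -> bool:
        """True when distinct fixed points match LL and SL."""
        return (
            "LL" in self.matched
            and "SL" in self.matched
            and self.matched["LL"] != self.matched["SL"]
        )


def validate_wildtype(
    net: BooleanNetwork, profiles: list[CellTypeProfile]
) -> WildtypeReport:
    """Classify every fixed point of ``net`` against the profiles.

    Profiles are restricted to the nodes the network actually has, so
    the NTT-free initial model is scored on its own node set (which is
    exactly how it fails: without NTT the restricted LL and SL profiles
    differ only in ALC, and no attractor has the ALC-off margin state).
    """
    aset = find_attractors(net)
    node_set = set(net.nodes)
    restricted = [
        CellTypeProfile(
            p.name,
            {k: v for k, v in p.marker_states.items() if k in node_set},
        )
        for p in profiles
    ]
    assignments = []
    matched: dict[str, int] = {}
    multi: set[str] = set()
    for a in aset.fixed_points:
        state = aset.state_dict(a.states[0])
        hits = [p.name for p in restricted if p.matches(state)]
        label = hits[0] if len(hits) == 1 else "novel"
        assignments.append((a.states[0], label))
        if label != "novel":
            if label in matched:
                multi.add(label)
            matched[label] = a.states[0]
    for name in multi:  # a profile matched twice is not uniquely matched
        del matched[name]
    unmatched = tuple(
        p.name for p in restricted if p.name not in matched
    )
    return WildtypeReport(
        attractors=aset,
        assignments=tuple(assignments),
        matched=matched,
        unmatched_profiles=unmatched,
    )
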
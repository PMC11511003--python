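"""Tabular output, run configuration, and test fixtures.

All tabular outputs are CSV with one header line and a fixed column
order (nodes as rows, canonically ordered attractors as columns), so
runs with identical configuration are byte-identical and diff-friendly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .attractors import AttractorSet
from .grn import CellTypeProfile, classify_state
from .network import BooleanNetwork, parse_rules, write_rules


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration written alongside every CLI output."""

    model: str = "final"
    seed: int = 0
    fraction: float = 0.1
    ensemble_size: int = 1000
    replicates: int = 10_000
    h: float = 10.0
    gamma: float = 1.0
    outdir: str = "."

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def attractor_frame(
    attractors: AttractorSet,
    profiles: list[CellTypeProfile] | None = None,
) -> pd.DataFrame:
    """Nodes x attractors 0/1 matrix with label/length/basin rows.

    Cyclic attractors contribute one column per cycle state, labelled
    ``cycle<i>.<k>``; fixed-point columns carry their profile label.
    """
    columns: dict[str, list[int]] = {}
    meta_label: dict[str, str] = {}
    meta_len: dict[str, int] = {}
    meta_basin: dict[str, int] = {}
    n_cycle = 0
    for a in attractors:
        if a.is_fixed_point:
            state = attractors.state_dict(a.states[0])
            label = classify_state(state, profiles)
            name = label
            k = 2
            while name in columns:  # disambiguate repeated labels
                name = f"{label}.{k}"
                k += 1
            columns[name] = list(attractors.decode(a.states[0]))
            meta_label[name], meta_len[name], meta_basin[name] = label, 1, a.basin_size
        else:
            n_cycle += 1
            for k, s in enumerate(a.states):
                name = f"cycle{n_cycle}.{k}"
                columns[name] = list(attractors.decode(s))
                meta_label[name] = "cycle"
                meta_len[name] = a.length
                meta_basin[name] = a.basin_size
    df = pd.DataFrame(columns, index=list(attractors.nodes))
    out = pd.concat(
        [
            df,
            pd.DataFrame(
                [meta_label, meta_len, meta_basin],
                index=["label", "length", "basin_size"],
            ),
        ]
    )
    out.index.name = "node"
    return out


def write_attractor_table(
    attractors: AttractorSet,
    profiles: list[CellTypeProfile] | None,
    path: str | Path,
) -> Path:
    """Write the attractor table as CSV (header-only when empty)."""
    path = Path(path)
    attractor_frame(attractors, profiles).to_csv(path)
    return path


def read_attractor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    return df


# --- fixtures ---------------------------------------------------------------

TOY_IDENTITY = "targets, factors\nA, A\n"
TOY_NEGATION = "targets, factors\nA, !A\n"
TOY_TOGGLE = "targets, factors\nA, !B\nB, !A\n"


def generate_fixtures(outdir: str | Path, seed: int = 20240) -> list[Path]:
    """Write the model files, catalogue/profile CSVs, three analytically
    solvable toy networks, and one seeded random 12-node network."""
    from importlib import resources

    from .robustness import random_network_like
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("initial.bnet", "final.bnet", "interactions.csv", "profiles.csv"):
        src = resources.files("dzgrn").joinpath("data", name)
        dst = outdir / name
        dst.write_text(src.read_text())
        written.append(dst)
    for name, text in (
        ("toy_identity.bnet", TOY_IDENTITY),
        ("toy_negation.bnet", TOY_NEGATION),
        ("toy_toggle.bnet", TOY_TOGGLE),
    ):
        dst = outdir / name
        dst.write_text(text)
        written.append(dst)
    final = parse_rules(
        resources.files("dzgrn").joinpath("data", "final.bnet").read_text()
    )
    rand = random_network_like(final, np.random.default_rng(seed))
    dst = outdir / "random12.bnet"
    dst.write_text(write_rules(rand))
    written.append(dst)
    return written
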
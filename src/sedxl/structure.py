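"""Mapping residue-level crosslinks onto structural models.

Crosslinked lysine pairs identified by MS carry a geometric constraint: the
linked residues cannot be farther apart than the crosslinker spacer allows
(30 A Calpha-Calpha for the amine-reactive linkers used here, a generous
ceiling that absorbs side-chain length and backbone flexibility). This
module reads coordinates, measures Calpha-Calpha distances for link pairs,
classifies restraint satisfaction at an inclusive ceiling, and writes
docking-ready distance restraints in the CNS/HADDOCK ``assign`` dialect.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "LinkRecord",
    "DistanceReport",
    "read_structure",
    "map_links",
    "link_distances",
    "write_restraints",
    "parse_restraints",
]

DEFAULT_CEILING_A = 30.0


@dataclass
class StructureModel:
    """Calpha coordinates per chain: chain id -> {residue number -> xyz (A)}."""

    chains: dict

    def get_ca(self, chain: str, resnum: int) -> np.ndarray | None:
        return self.chains.get(chain, {}).get(resnum)

    def chain_length(self, chain: str) -> int:
        return len(self.chains.get(chain, {}))


@dataclass(frozen=True)
class LinkRecord:
    """A residue-level crosslink in full-protein 1-based numbering."""

    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    linker: str = ""

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("residue positions are 1-based and must be >= 1")


@dataclass
class DistanceReport:
    """Measured model distances vs the restraint ceiling for a set of links.

    ``table`` has one row per link with measured_distance_A (NaN when
    unresolved), satisfied and unresolved flags. Unresolved links (residue
    absent from the model) are excluded from the satisfied/violated counts.
    """

    table: pd.DataFrame
    ceiling_A: float

    @property
    def n_satisfied(self) -> int:
        return int((self.table["satisfied"] & ~self.table["unresolved"]).sum())

    @property
    def n_violated(self) -> int:
        return int((~self.table["satisfied"] & ~self.table["unresolved"]).sum())

    @property
    def n_unresolved(self) -> int:
        return int(self.table["unresolved"].sum())

    def summary(self) -> str:
        return (
            f"crosslink restraint check at {self.ceiling_A:.1f} A ceiling: "
            f"{self.n_satisfied} satisfied, {self.n_violated} violated, "
            f"{self.n_unresolved} unresolved"
        )


def read_structure(pdb_path: str | Path) -> StructureModel:
    """Parse Calpha coordinates from a PDB file (first model only).

    Alternate locations are resolved to the highest-occupancy conformer;
    insertion codes are rejected (renumber the model first); duplicate
    residue numbers within a chain are an error.
    """
    import gemmi

    st = gemmi.read_structure(str(pdb_path))
    if len(st) == 0:
        raise ValueError(f"{pdb_path}: no models")
    model = st[0]
    chains: dict = {}
    found_ca = False
    for chain in model:
        per = {}
        for res in chain:
            if res.seqid.icode not in (" ", "\x00", ""):
                raise ValueError(
                    f"{pdb_path}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name}:{res.seqid.num} not supported"
                )
            best = None
            for atom in res:
                if atom.name == "CA":
                    if best is None or atom.occ > best.occ:
                        best = atom
            if best is None:
                continue
            found_ca = True
            if res.seqid.num in per:
                raise ValueError(
                    f"{pdb_path}: duplicate residue number {chain.name}:{res.seqid.num}"
                )
            per[res.seqid.num] = np.array([best.pos.x, best.pos.y, best.pos.z])
        if per:
            chains[chain.name] = per
    if not found_ca:
        raise ValueError(f"{pdb_path}: no Calpha atoms found")
    return StructureModel(chains=chains)


def map_links(
    links: list[LinkRecord],
    chain_map: dict[str, str],
    offset_map: dict[str, int] | None = None,
) -> list[tuple]:
    """Translate full-protein link positions into model (chain, residue)
    pairs.

    ``offset_map`` shifts numbering per protein (model residue number =
    full-protein position + offset), accommodating models that omit leading
    residues. Every linked protein must appear in ``chain_map``.

    Returns ``[(chain_a, resnum_a, chain_b, resnum_b, link), ...]``.
    """
    offset_map = offset_map or {}
    out = []
    for link in links:
        for prot in (link.protein_a, link.protein_b):
            if prot not in chain_map:
                raise KeyError(f"protein {prot!r} missing from chain_map")
        out.append(
            (
                chain_map[link.protein_a],
                link.pos_a + offset_map.get(link.protein_a, 0),
                chain_map[link.protein_b],
                link.pos_b + offset_map.get(link.protein_b, 0),
                link,
            )
        )
    return out


def link_distances(
    model: StructureModel,
    pairs: list[tuple],
    ceiling_A: float = DEFAULT_CEILING_A,
) -> DistanceReport:
    """Euclidean Calpha-Calpha distance for each mapped pair, classified
    against an inclusive ceiling (distance == ceiling counts as satisfied).

    Pairs whose residues are missing from the model are flagged unresolved
    rather than raising.
    """
    rows = []
    for entry in pairs:
        chain_a, res_a, chain_b, res_b = entry[:4]
        xa = model.get_ca(chain_a, res_a)
        xb = model.get_ca(chain_b, res_b)
        if xa is None or xb is None:
            rows.append(
                {
                    "chain_a": chain_a,
                    "res_a": res_a,
                    "chain_b": chain_b,
                    "res_b": res_b,
                    "measured_distance_A": math.nan,
                    "satisfied": False,
                    "unresolved": True,
                }
            )
            continue
        d = float(np.linalg.norm(xa - xb))
        rows.append(
            {
                "chain_a": chain_a,
                "res_a": res_a,
                "chain_b": chain_b,
                "res_b": res_b,
                "measured_distance_A": d,
                "satisfied": d <= ceiling_A,
                "unresolved": False,
            }
        )
    cols = [
        "chain_a",
        "res_a",
        "chain_b",
        "res_b",
        "measured_distance_A",
        "satisfied",
        "unresolved",
    ]
    return DistanceReport(table=pd.DataFrame(rows, columns=cols), ceiling_A=ceiling_A)


_ASSIGN_RE = re.compile(
    r"assign\s+\(segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+CA\)\s+"
    r"\(segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+CA\)\s+"
    r"([\d.]+)\s+([\d.]+)\s+([\d.]+)"
)


def write_restraints(
    pairs: list[tuple], ceiling_A: float, path: str | Path
) -> Path:
    """Write unambiguous Calpha distance restraints in the CNS/HADDOCK
    ``assign`` dialect, one line per unique pair:

        assign (segid A and resid 50 and name CA)
               (segid B and resid 35 and name CA) 30.0 30.0 0.0

    (target d = ceiling, lower bound d - d^- = 0, upper slack d^+ = 0: the
    pair may come anywhere up to the ceiling). Duplicate pairs are collapsed;
    an empty pair list produces a file with only the header comment.
    """
    path = Path(path)
    seen = set()
    lines = ["! Calpha-Calpha crosslink distance restraints"]
    for entry in pairs:
        chain_a, res_a, chain_b, res_b = entry[:4]
        key = (chain_a, res_a, chain_b, res_b)
        if key in seen:
            continue
        seen.add(key)
        lines.append(
            f"assign (segid {chain_a} and resid {res_a} and name CA) "
            f"(segid {chain_b} and resid {res_b} and name CA) "
            f"{ceiling_A:.1f} {ceiling_A:.1f} 0.0"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_restraints(path: str | Path) -> list[tuple]:
    """Parse an ``assign``-dialect restraint file back into
    ``(chain_a, res_a, chain_b, res_b)`` tuples (round-trip of
    :func:`write_restraints`)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        m = _ASSIGN_RE.match(line)
        if not m:
            raise ValueError(f"unparseable restraint line: {line!r}")
        out.append((m.group(1), int(m.group(2)), m.group(3), int(m.group(4))))
    return out
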
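"""In-silico tryptic digestion with crosslink-aware site bookkeeping.

Trypsin cleaves C-terminal to K and R except when the next residue is
proline. Peptides carrying a crosslinked lysine necessarily contain a
missed cleavage (the modified K is not cut), so the default allows up to 3.
Monoisotopic masses come from pyteomics' residue tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

__all__ = ["ProteinEntry", "DigestParams", "Peptide", "digest", "peptide_mass", "read_fasta"]

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinEntry:
    """A protein sequence (FASTA-sourced or synthetic)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - CANONICAL
        if bad:
            raise ValueError(f"non-canonical residues in {self.id!r}: {sorted(bad)}")

    def reversed(self, prefix: str = "DECOY_") -> "ProteinEntry":
        """Reversed-sequence decoy counterpart."""
        return ProteinEntry(id=prefix + self.id, sequence=self.sequence[::-1])


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion settings: missed cleavages and peptide filters."""

    max_missed_cleavages: int = 3
    min_len: int = 6
    max_len: int = 60
    min_mass: float = 600.0
    max_mass: float = 6000.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len or self.min_mass > self.max_mass:
            raise ValueError("min must not exceed max for length and mass filters")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 1-based inclusive protein coordinates and
    the residue positions (protein coordinates) available for crosslinking."""

    protein_id: str
    start: int
    end: int
    sequence: str
    monoisotopic_mass: float
    linkable_positions: tuple = ()
    missed_cleavages: int = 0


def peptide_mass(sequence: str) -> float:
    """Monoisotopic neutral peptide mass (residues + water), Da.

    No fixed or variable modifications are considered.
    """
    return _pmass.fast_mass(sequence)


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between residue i and i+1
    (after K/R, not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def _linkable(sequence: str, start: int, end: int, protein_len: int) -> tuple:
    """Crosslinkable residue positions, in 1-based protein coordinates.

    Lysines anywhere except the peptide C-terminus (a linker-modified K is
    not cleaved, so a C-terminal K implies the link is elsewhere — unless
    the peptide ends at the protein C-terminus), plus the alpha-amine when
    the peptide starts at position 1.
    """
    sites = []
    if start == 1:
        sites.append(1)
    for off, aa in enumerate(sequence):
        pos = start + off
        if aa == "K" and (pos != end or end == protein_len) and pos not in sites:
            sites.append(pos)
    return tuple(sites)


def digest(protein: ProteinEntry, params: DigestParams | None = None) -> list[Peptide]:
    """Tryptic peptides of ``protein`` with 0..max missed cleavages,
    filtered by length and monoisotopic mass.

    Peptides are returned in order of start position, then end position.
    """
    params = params or DigestParams()
    seq = protein.sequence
    n = len(seq)
    cuts = cleavage_sites(seq)
    # fragment boundaries: starts after each cut, plus 0; ends at each cut+1, plus n
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [n]
    peptides = []
    for i, a in enumerate(starts):
        for j in range(i, min(i + params.max_missed_cleavages + 1, len(ends))):
            b = ends[j]
            pep = seq[a:b]
            if not params.min_len <= len(pep) <= params.max_len:
                continue
            m = peptide_mass(pep)
            if not params.min_mass <= m <= params.max_mass:
                continue
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=a + 1,
                    end=b,
                    sequence=pep,
                    monoisotopic_mass=m,
                    linkable_positions=_linkable(pep, a + 1, b, n),
                    missed_cleavages=j - i,
                )
            )
    return peptides


def read_fasta(path) -> list[ProteinEntry]:
    """Read protein entries from FASTA via Biopython."""
    from Bio import SeqIO

    return [
        ProteinEntry(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
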
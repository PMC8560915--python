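"""Reported crosslinked peptide pairs for the nematode CDC-37/DNJ-13
chaperone co-factor system.

These are the experimentally identified lysine-lysine (and alpha-amine)
crosslinks between C. elegans CDC-37 and DNJ-13, from isotope-coded
BS3/DSSG crosslinking followed by MS: sample "a" is the ~135 kDa complex of
one CDC-37 with a DNJ-13 dimer, sample "b" a larger (>245 kDa) assembly,
sample "c" the DNJ-13 dimer reference (intra- and intermolecular links).
Positions are 1-based residue numbers of the linked residue in the full
protein. The full protein sequences are not part of this table; the pairs
serve as ground truth for synthetic peak-list generation and as link
records for structural restraint validation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReportedLink", "REPORTED_LINKS", "intermolecular_pairs"]


@dataclass(frozen=True)
class ReportedLink:
    peptide_a: str
    peptide_b: str
    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    sample: str  # "a" (135 kDa complex), "b" (>245 kDa), "c" (DNJ-13 dimer)


REPORTED_LINKS: tuple[ReportedLink, ...] = (
    # sample a: CDC-37 + DNJ-13 dimer complex (~135 kDa), intermolecular
    ReportedLink("EAGAENKFK", "GTTSKK", "DNJ-13", 44, "CDC-37", 60, "a"),
    ReportedLink("MEQEKIDK", "YHPDKNK", "CDC-37", 50, "DNJ-13", 35, "a"),
    ReportedLink("GKDYYKVLGISK", "EKGTTSK", "DNJ-13", 3, "CDC-37", 55, "a"),
    ReportedLink("KMK", "ITRKPQAPK", "DNJ-13", 179, "CDC-37", 132, "a"),
    ReportedLink("MEQEKIDK", "YHPDKNK", "CDC-37", 50, "DNJ-13", 35, "a"),
    ReportedLink("AYRKMALK", "MEELEKK", "DNJ-13", 26, "CDC-37", 67, "a"),
    ReportedLink("MGKDYYK", "GTTSKK", "DNJ-13", 1, "CDC-37", 60, "a"),
    ReportedLink("MPIDYSK", "GTTKKMK", "CDC-37", 1, "DNJ-13", 176, "a"),
    ReportedLink("AYRKMALK", "GTTSKK", "DNJ-13", 26, "CDC-37", 60, "a"),
    ReportedLink("GLPNPKSPSHR", "PIDYSK", "DNJ-13", 299, "CDC-37", 2, "a"),
    ReportedLink("KEAELEEK", "MGKDYYK", "CDC-37", 97, "DNJ-13", 3, "a"),
    ReportedLink("LERMAEK", "KDKPHPK", "CDC-37", 44, "DNJ-13", 235, "a"),
    # sample b: larger assembly (> 245 kDa), intermolecular
    ReportedLink("KFEAAEPVYMK", "MGKDYYK", "CDC-37", 241, "DNJ-13", 1, "b"),
    ReportedLink("MEQEKIDK", "YHPDKNK", "CDC-37", 50, "DNJ-13", 35, "b"),
    ReportedLink("MEELEKKLAAADVTDKK", "MALKYHPDK", "CDC-37", 67, "DNJ-13", 30, "b"),
    ReportedLink("MEQEKIDK", "YHPDKNK", "CDC-37", 50, "DNJ-13", 35, "b"),
    # sample c: DNJ-13 dimer reference, intra- and intermolecular
    ReportedLink("DYYKVLGISK", "GATDDEIKK", "DNJ-13", 7, "DNJ-13", 21, "c"),
    ReportedLink("GATDDEIKK", "YHPDKNK", "DNJ-13", 21, "DNJ-13", 35, "c"),
    ReportedLink("GLPNPKSPSHR", "GATDDEIKK", "DNJ-13", 299, "DNJ-13", 21, "c"),
    ReportedLink("KVMTDNAQR", "EAGAENKFK", "DNJ-13", 183, "DNJ-13", 44, "c"),
    ReportedLink("DYYKVLGISK", "EAGAENKFK", "DNJ-13", 7, "DNJ-13", 44, "c"),
    ReportedLink("NKEAGAENK", "GKDYYK", "DNJ-13", 37, "DNJ-13", 3, "c"),
    ReportedLink("KIYDQFGEEGLK", "GATDDEIKK", "DNJ-13", 62, "DNJ-13", 21, "c"),
    ReportedLink("VLGISKGATDDEIKK", "EAGAENKFK", "DNJ-13", 13, "DNJ-13", 44, "c"),
    ReportedLink("EIAEAYDVLSDDKKK", "KIYDQFGEEGLK", "DNJ-13", 59, "DNJ-13", 62, "c"),
    ReportedLink("VEKISLK", "EGSDIKR", "DNJ-13", 252, "DNJ-13", 248, "c"),
    ReportedLink("EAGAENKFK", "GATDDEIKK", "DNJ-13", 44, "DNJ-13", 21, "c"),
    ReportedLink("DYYKVLGISK", "EGSDIKR", "DNJ-13", 7, "DNJ-13", 248, "c"),
)


def intermolecular_pairs(sample: str = "a") -> list[ReportedLink]:
    """Links from one sample, duplicates retained (multiplicity matters for
    reporting tests)."""
    return [l for l in REPORTED_LINKS if l.sample == sample]
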
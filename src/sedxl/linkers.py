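"""Isotope-coded amine-reactive crosslinker chemistry.

BS3 (bis-sulfosuccinimidyl suberate) and DSSG (disuccinimidyl glutarate)
are homobifunctional NHS esters that bridge primary amines — lysine side
chains and the protein N-terminal alpha-amine. Supplied as 1:1 mixtures of
the protonated and per-deuterated reagent (H12/D12 for BS3, H6/D6 for
DSSG), every crosslinked product appears in MS1 as a light/heavy doublet
separated by n_D x (m(2H) - m(1H)), a signature that distinguishes genuine
crosslinks from ordinary peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import DEUTERIUM_DELTA

__all__ = ["LinkerSpec", "LINKERS", "get_linker"]


@dataclass(frozen=True)
class LinkerSpec:
    """A crosslinker: the residual bridge mass added to the summed peptide
    masses (light form, monoisotopic Da) and the heavy-isotope shift."""

    name: str
    bridge_mass_light: float  # Da, monoisotopic
    n_deuterium: int
    reactive_sites: tuple = ("K", "protein_nterm")

    def __post_init__(self) -> None:
        if self.bridge_mass_light <= 0:
            raise ValueError("bridge mass must be positive")

    @property
    def heavy_delta(self) -> float:
        """Neutral-mass difference between heavy and light products, Da."""
        return self.n_deuterium * DEUTERIUM_DELTA


#: Registered chemistries. Bridge = linker minus both NHS leaving groups:
#: C8H10O2 for the suberate bridge, C5H4O2 for the glutarate bridge.
LINKERS: dict[str, LinkerSpec] = {
    "BS3": LinkerSpec(name="BS3", bridge_mass_light=138.06808, n_deuterium=12),
    "DSSG": LinkerSpec(name="DSSG", bridge_mass_light=96.02113, n_deuterium=6),
}


def get_linker(name: str) -> LinkerSpec:
    try:
        return LINKERS[name]
    except KeyError:
        raise KeyError(f"unknown linker {name!r}; registered: {sorted(LINKERS)}") from None
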
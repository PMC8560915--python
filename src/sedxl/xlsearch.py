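"""MS1-level identification of isotope-coded crosslinked peptide pairs.

The search enumerates candidate crosslinked pair masses from in-silico
digests, then demands that BOTH members of the light/heavy isotope doublet
be present in the MS1 peak list at the same charge: a light peak within the
precursor tolerance of the candidate m/z and a heavy peak shifted by the
linker's deuterium delta, with a plausible intensity ratio and co-elution.
Decoy candidates built from reversed protein sequences calibrate a
target-decoy false-discovery rate, and accepted hits are further refined by
a tight final mass-error filter.

Fragment-level (MS2) scoring is out of scope; the doublet requirement is
what makes MS1-only identification specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import PROTON_MASS
from .digest import DigestParams, Peptide, ProteinEntry, digest
from .linkers import LinkerSpec

__all__ = [
    "CrosslinkCandidate",
    "CrosslinkHit",
    "enumerate_candidates",
    "match_doublets",
    "filter_fdr",
    "report_links",
    "search",
]


@dataclass(frozen=True)
class CrosslinkCandidate:
    """An enumerated crosslinked peptide pair and its light neutral mass."""

    peptide_a: Peptide
    peptide_b: Peptide
    linker: LinkerSpec
    light_mass: float  # neutral, Da
    is_decoy: bool
    is_intra: bool

    @property
    def heavy_mass(self) -> float:
        return self.light_mass + self.linker.heavy_delta

    def mz(self, z: int, heavy: bool = False) -> float:
        m = self.heavy_mass if heavy else self.light_mass
        return (m + z * PROTON_MASS) / z


@dataclass(frozen=True)
class CrosslinkHit:
    """A doublet match between a candidate and two observed MS1 peaks."""

    candidate: CrosslinkCandidate
    charge: int
    observed_light_mass: float
    observed_heavy_mass: float
    ppm_error: float
    doublet_intensity_ratio: float
    rt_min: float
    score: float
    qvalue: float = math.nan

    @property
    def is_decoy(self) -> bool:
        return self.candidate.is_decoy


def _pep_key(p: Peptide) -> tuple:
    return (p.protein_id, p.start, p.end, p.sequence)


def enumerate_candidates(
    peps_a: list[Peptide],
    peps_b: list[Peptide],
    linker: LinkerSpec,
) -> list[CrosslinkCandidate]:
    """All unordered pairs of linkable peptides with the linker bridge.

    Both peptides must carry at least one linkable site (lysine away from a
    cleavable C-terminus, or the protein N-terminal alpha-amine). The pair's
    light neutral mass is m_a + m_b + bridge; pairs are unordered, so the
    result is invariant under swapping the input lists. Intra-protein pairs
    are tagged; a pair is a decoy pair if either peptide comes from a decoy
    (reversed) protein.
    """
    if not peps_a or not peps_b:
        raise ValueError("peptide lists must be non-empty")
    la = [p for p in peps_a if p.linkable_positions]
    lb = [p for p in peps_b if p.linkable_positions]
    seen: set = set()
    out = []
    for pa in la:
        for pb in lb:
            ka, kb = _pep_key(pa), _pep_key(pb)
            key = (ka, kb) if ka <= kb else (kb, ka)
            if key in seen:
                continue
            seen.add(key)
            a, b = (pa, pb) if ka <= kb else (pb, pa)
            light = a.monoisotopic_mass + b.monoisotopic_mass + linker.bridge_mass_light
            out.append(
                CrosslinkCandidate(
                    peptide_a=a,
                    peptide_b=b,
                    linker=linker,
                    light_mass=light,
                    is_decoy=a.protein_id.startswith("DECOY_")
                    or b.protein_id.startswith("DECOY_"),
                    is_intra=a.protein_id.removeprefix("DECOY_")
                    == b.protein_id.removeprefix("DECOY_"),
                )
            )
    return out


def match_doublets(
    peaklist: pd.DataFrame,
    candidates: list[CrosslinkCandidate],
    precursor_ppm: float = 15.0,
    delta_ppm: float = 15.0,
    ratio_window: tuple[float, float] = (0.3, 3.3),
    charges: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    rt_tol_min: float = 0.5,
    require_coelution: bool = True,
) -> list[CrosslinkHit]:
    """Match candidates against MS1 peaks as light/heavy doublets.

    A hit requires, at one charge state, a light peak within
    ``precursor_ppm`` of the candidate light m/z AND a heavy peak within
    ``delta_ppm`` of the deuterium-shifted m/z, heavy/light intensity ratio
    inside ``ratio_window`` and (optionally) co-elution within
    ``rt_tol_min``. Each observed peak pair is assigned to at most one
    candidate — the one with the lowest light-peak |ppm| error, ties broken
    toward the lower candidate mass. Score is -|ppm error|.

    ``peaklist`` needs columns mz, z, intensity and (if co-elution is
    required) rt_min. An empty peak list yields an empty result.
    """
    if len(peaklist) == 0 or not candidates:
        return []
    need = {"mz", "z", "intensity"}
    if not need.issubset(peaklist.columns):
        raise ValueError(f"peak list must have columns {sorted(need)}")
    has_rt = "rt_min" in peaklist.columns
    if require_coelution and not has_rt:
        require_coelution = False

    by_z = {}
    for z in sorted(set(int(v) for v in peaklist["z"])):
        sub = peaklist[peaklist["z"] == z].sort_values("mz").reset_index()
        by_z[z] = (
            sub["mz"].to_numpy(),
            sub["intensity"].to_numpy(),
            sub["rt_min"].to_numpy() if has_rt else np.zeros(len(sub)),
            sub["index"].to_numpy(),
        )

    matches: dict[tuple, tuple] = {}  # (light_row, heavy_row) -> (|ppm|, mass, hit)
    for cand in candidates:
        for z in charges:
            if z not in by_z:
                continue
            mzs, inten, rts, rows = by_z[z]
            lmz = cand.mz(z)
            tol = lmz * precursor_ppm * 1e-6
            i0, i1 = np.searchsorted(mzs, [lmz - tol, lmz + tol])
            for i in range(i0, i1):
                hmz = cand.mz(z, heavy=True)
                htol = hmz * delta_ppm * 1e-6
                j0, j1 = np.searchsorted(mzs, [hmz - htol, hmz + htol])
                for j in range(j0, j1):
                    ratio = inten[j] / inten[i] if inten[i] > 0 else math.inf
                    if not ratio_window[0] <= ratio <= ratio_window[1]:
                        continue
                    if require_coelution and abs(rts[j] - rts[i]) > rt_tol_min:
                        continue
                    ppm = (mzs[i] - lmz) / lmz * 1e6
                    hit = CrosslinkHit(
                        candidate=cand,
                        charge=z,
                        observed_light_mass=mzs[i] * z - z * PROTON_MASS,
                        observed_heavy_mass=mzs[j] * z - z * PROTON_MASS,
                        ppm_error=ppm,
                        doublet_intensity_ratio=ratio,
                        rt_min=float(rts[i]),
                        score=-abs(ppm),
                    )
                    key = (int(rows[i]), int(rows[j]))
                    prev = matches.get(key)
                    # tie-break: |ppm| (quantized: summation-order float
                    # noise is not a real difference), then target before
                    # decoy — reversed decoy pairs can be exactly isobaric
                    # with targets since reversal conserves composition, and
                    # standard target-decoy competition gives exact ties to
                    # the target — then lower mass
                    rank = (round(abs(ppm), 4), cand.is_decoy, cand.light_mass)
                    if prev is None or rank < prev[0]:
                        matches[key] = (rank, hit)
    return sorted(
        (v[1] for v in matches.values()), key=lambda h: (-h.score, h.candidate.light_mass)
    )


def filter_fdr(
    hits: list[CrosslinkHit], fdr_max: float = 0.05, final_ppm: float = 2.0
) -> list[CrosslinkHit]:
    """Target-decoy FDR control followed by a tight mass-error refinement.

    Hits are ranked by score; at each threshold the FDR estimate is
    (decoys)/(targets) among hits scoring at least as well, made monotone by
    a cumulative minimum from the best score down (so q-values never
    decrease as the score worsens). Target hits with q <= ``fdr_max`` AND
    |ppm error| < ``final_ppm`` survive; decoys are dropped from the output.
    """
    targets_exist = any(not h.is_decoy for h in hits)
    if not targets_exist:
        return []
    ranked = sorted(hits, key=lambda h: -h.score)
    n_t = n_d = 0
    fdrs = []
    for h in ranked:
        if h.is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(n_d / n_t if n_t else math.inf)
    # monotone q-values: q_i = min_{j >= i} fdr_j
    q = np.minimum.accumulate(np.asarray(fdrs)[::-1])[::-1]
    out = []
    for h, qv in zip(ranked, q):
        if h.is_decoy:
            continue
        if qv <= fdr_max and abs(h.ppm_error) < final_ppm:
            out.append(replace(h, qvalue=float(qv)))
    return out


def report_links(hits: list[CrosslinkHit], proteins: list[ProteinEntry] | None = None
                 ) -> pd.DataFrame:
    """Collapse hits into a residue-level link table.

    One row per unique (peptide_a, peptide_b, site_a, site_b) with 1-based
    full-protein positions of the linked residues (the most N-terminal
    linkable site of each peptide), a multiplicity count of collapsed hits,
    and an intra/inter tag. Returns an empty table with the full header when
    there are no hits.
    """
    cols = [
        "peptide_a",
        "peptide_b",
        "protein_a",
        "pos_a",
        "protein_b",
        "pos_b",
        "linker",
        "best_ppm",
        "qvalue",
        "multiplicity",
        "link_type",
    ]
    known = {p.id for p in proteins} if proteins is not None else None
    rows: dict[tuple, dict] = {}
    for h in hits:
        c = h.candidate
        if known is not None:
            for pid in (c.peptide_a.protein_id, c.peptide_b.protein_id):
                if pid not in known:
                    raise ValueError(f"hit references unknown protein {pid!r}")
        pos_a = c.peptide_a.linkable_positions[0]
        pos_b = c.peptide_b.linkable_positions[0]
        key = (c.peptide_a.sequence, c.peptide_b.sequence, pos_a, pos_b)
        if key in rows:
            rows[key]["multiplicity"] += 1
            rows[key]["best_ppm"] = min(rows[key]["best_ppm"], abs(h.ppm_error))
            if not math.isnan(h.qvalue):
                rows[key]["qvalue"] = min(rows[key]["qvalue"], h.qvalue)
        else:
            rows[key] = {
                "peptide_a": c.peptide_a.sequence,
                "peptide_b": c.peptide_b.sequence,
                "protein_a": c.peptide_a.protein_id,
                "pos_a": pos_a,
                "protein_b": c.peptide_b.protein_id,
                "pos_b": pos_b,
                "linker": c.linker.name,
                "best_ppm": abs(h.ppm_error),
                "qvalue": h.qvalue,
                "multiplicity": 1,
                "link_type": "intra" if c.is_intra else "inter",
            }
    return pd.DataFrame(list(rows.values()), columns=cols)


def search(
    proteins: list[ProteinEntry],
    peaklist: pd.DataFrame,
    linker: LinkerSpec,
    digest_params: DigestParams | None = None,
    precursor_ppm: float = 15.0,
    fdr_max: float = 0.05,
    final_ppm: float = 2.0,
    with_decoys: bool = True,
    **match_kwargs,
) -> pd.DataFrame:
    """End-to-end crosslink search: digest targets (and reversed decoys),
    enumerate pairs, match doublets, control FDR, report links."""
    digest_params = digest_params or DigestParams()
    entries = list(proteins)
    if with_decoys:
        entries += [p.reversed() for p in proteins]
    peps = []
    for p in entries:
        peps.extend(digest(p, digest_params))
    cands = enumerate_candidates(peps, peps, linker)
    hits = match_doublets(
        peaklist, cands, precursor_ppm=precursor_ppm, delta_ppm=precursor_ppm, **match_kwargs
    )
    accepted = filter_fdr(hits, fdr_max=fdr_max, final_ppm=final_ppm)
    return report_links(accepted, entries)
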
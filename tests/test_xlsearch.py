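"""Isotope-doublet crosslink search: candidate mass arithmetic, doublet
matching, target-decoy FDR control, and link reporting."""

import math

import numpy as np
import pandas as pd
import pytest
from pyteomics import mass as pmass

from sedxl.constants import PROTON_MASS
from sedxl.digest import DigestParams, Peptide, ProteinEntry, digest, peptide_mass
from sedxl.linkers import get_linker
from sedxl.refdata import intermolecular_pairs
from sedxl.simulate import PeakListSpec, gen_peaklist
from sedxl.xlsearch import (
    enumerate_candidates,
    filter_fdr,
    match_doublets,
    report_links,
    search,
)


def mk_pep(seq, prot="P1", start=100):
    ks = tuple(start + i for i, a in enumerate(seq[:-1]) if a == "K")
    return Peptide(
        protein_id=prot,
        start=start,
        end=start + len(seq) - 1,
        sequence=seq,
        monoisotopic_mass=peptide_mass(seq),
        linkable_positions=ks or (start,),
    )


class TestCandidateMasses:
    def test_bs3_worked_example(self):
        """(EAGAENKFK, GTTSKK) + BS3: light mass is the residue-sum masses
        plus the suberate bridge; heavy is 12 deuteriums up."""
        cands = enumerate_candidates(
            [mk_pep("EAGAENKFK", "DNJ-13", 38)], [mk_pep("GTTSKK", "CDC-37", 56)],
            get_linker("BS3"),
        )
        assert len(cands) == 1
        c = cands[0]
        # oracle: residue-mass summation + water, computed independently
        m_a = sum(pmass.std_aa_mass[x] for x in "EAGAENKFK") + 18.0105646
        m_b = sum(pmass.std_aa_mass[x] for x in "GTTSKK") + 18.0105646
        assert c.light_mass == pytest.approx(m_a + m_b + 138.06808, abs=1e-4)
        assert c.light_mass == pytest.approx(1750.91013, abs=1e-3)
        assert c.heavy_mass - c.light_mass == pytest.approx(12.07532, abs=1e-4)

    def test_dssg_heavy_delta(self):
        cands = enumerate_candidates(
            [mk_pep("MEQEKIDK", "CDC-37", 46)], [mk_pep("YHPDKNK", "DNJ-13", 31)],
            get_linker("DSSG"),
        )
        c = cands[0]
        assert c.heavy_mass - c.light_mass == pytest.approx(6.03766, abs=1e-4)

    def test_unordered_pairs_symmetric_under_list_swap(self):
        a = [mk_pep("EAGAENKFK", "X", 10), mk_pep("AYRKMALK", "X", 40)]
        b = [mk_pep("GTTSKK", "Y", 20)]
        ab = enumerate_candidates(a, b, get_linker("BS3"))
        ba = enumerate_candidates(b, a, get_linker("BS3"))
        key = lambda c: (c.peptide_a.sequence, c.peptide_b.sequence)
        assert sorted(map(key, ab)) == sorted(map(key, ba))

    def test_peptide_without_linkable_site_excluded(self):
        no_k = Peptide(
            protein_id="Z", start=1, end=6, sequence="AAADDE",
            monoisotopic_mass=peptide_mass("AAADDE"), linkable_positions=(),
        )
        cands = enumerate_candidates([no_k, mk_pep("GTTSKK")], [mk_pep("EAGAENKFK")],
                                     get_linker("BS3"))
        assert all(c.peptide_a.sequence != "AAADDE" and c.peptide_b.sequence != "AAADDE"
                   for c in cands)


def _planted_fixture(jitter_sd=2.0, decoys=0, seed=11, linker="BS3", charges=(2, 3, 4)):
    links = intermolecular_pairs("a")
    pairs = [(l.peptide_a, l.peptide_b, linker) for l in links]
    spec = PeakListSpec(
        pairs=pairs, charges=charges, ppm_jitter_sd=jitter_sd,
        decoy_peak_count=decoys, seed=seed,
    )
    peaks, truth = gen_peaklist(spec)
    peps = {}
    for l in links:
        peps.setdefault(l.peptide_a, mk_pep(l.peptide_a, l.protein_a, l.pos_a))
        peps.setdefault(l.peptide_b, mk_pep(l.peptide_b, l.protein_b, l.pos_b))
    cands = enumerate_candidates(list(peps.values()), list(peps.values()),
                                 get_linker(linker))
    planted = {tuple(sorted((l.peptide_a, l.peptide_b))) for l in links}
    return peaks, cands, planted


class TestMatchDoublets:
    def test_empty_peaklist_gives_no_hits(self):
        peaks = pd.DataFrame(columns=["mz", "z", "intensity", "rt_min"])
        assert match_doublets(peaks, [
            enumerate_candidates([mk_pep("GTTSKK")], [mk_pep("EAGAENKFK")],
                                 get_linker("BS3"))[0]
        ]) == []

    def test_all_planted_pairs_recovered_no_false_hits(self):
        peaks, cands, planted = _planted_fixture(jitter_sd=2.0, decoys=0, seed=11)
        hits = match_doublets(peaks, cands)
        got = {tuple(sorted((h.candidate.peptide_a.sequence,
                             h.candidate.peptide_b.sequence))) for h in hits}
        assert got == planted

    def test_light_without_heavy_is_not_a_hit(self):
        cand = enumerate_candidates([mk_pep("GTTSKK")], [mk_pep("EAGAENKFK")],
                                    get_linker("BS3"))[0]
        peaks = pd.DataFrame(
            {"mz": [cand.mz(2)], "z": [2], "intensity": [1e6], "rt_min": [30.0]}
        )
        assert match_doublets(peaks, [cand]) == []

    def test_intensity_ratio_window_enforced(self):
        cand = enumerate_candidates([mk_pep("GTTSKK")], [mk_pep("EAGAENKFK")],
                                    get_linker("BS3"))[0]
        peaks = pd.DataFrame(
            {
                "mz": [cand.mz(2), cand.mz(2, heavy=True)],
                "z": [2, 2],
                "intensity": [1e6, 1e4],  # ratio 0.01, outside [0.3, 3.3]
                "rt_min": [30.0, 30.0],
            }
        )
        assert match_doublets(peaks, [cand]) == []

    def test_coelution_required(self):
        cand = enumerate_candidates([mk_pep("GTTSKK")], [mk_pep("EAGAENKFK")],
                                    get_linker("BS3"))[0]
        peaks = pd.DataFrame(
            {
                "mz": [cand.mz(2), cand.mz(2, heavy=True)],
                "z": [2, 2],
                "intensity": [1e6, 1e6],
                "rt_min": [30.0, 45.0],
            }
        )
        assert match_doublets(peaks, [cand]) == []
        assert len(match_doublets(peaks, [cand], require_coelution=False)) == 1

    def test_perfect_input_matches_at_zero_ppm(self):
        peaks, cands, planted = _planted_fixture(jitter_sd=0.0, decoys=0, seed=5)
        hits = match_doublets(peaks, cands)
        assert len(hits) > 0
        assert max(abs(h.ppm_error) for h in hits) < 1e-6

    def test_heavy_jitter_destroys_recovery(self):
        """Jitter far beyond the tolerance: recovery collapses below 5%."""
        links = [l for s in "abc" for l in intermolecular_pairs(s)]
        pairs = [(l.peptide_a, l.peptide_b, "BS3") for l in links]
        spec = PeakListSpec(pairs=pairs, charges=(2, 3, 4), ppm_jitter_sd=200.0, seed=5)
        peaks, _ = gen_peaklist(spec)
        peps = {}
        for l in links:
            peps.setdefault(l.peptide_a, mk_pep(l.peptide_a, l.protein_a, l.pos_a))
            peps.setdefault(l.peptide_b, mk_pep(l.peptide_b, l.protein_b, l.pos_b))
        cands = enumerate_candidates(list(peps.values()), list(peps.values()),
                                     get_linker("BS3"))
        planted = {tuple(sorted((l.peptide_a, l.peptide_b))) for l in links}
        hits = match_doublets(peaks, cands)
        got = {tuple(sorted((h.candidate.peptide_a.sequence,
                             h.candidate.peptide_b.sequence))) for h in hits}
        assert len(got & planted) / len(planted) < 0.05


def _target_decoy_fixture(seed=4):
    """Two synthetic proteins (sequences labeled synthetic, assembled from
    lysine-containing tryptic-style segments), reversed decoys, 40 planted
    candidate doublets and 10% random decoy peaks."""
    rng = np.random.default_rng(seed)
    aas = np.array(list("ADEFGHILNQSTVWY"))  # no K/R/P/M/C: inert filler

    def synth_protein(pid, n_segments=12):
        parts = []
        for _ in range(n_segments):
            seg = "".join(rng.choice(aas, size=int(rng.integers(3, 9))))
            parts.append(seg + "K" + "".join(rng.choice(aas, size=2)) + "R")
        return ProteinEntry(id=pid, sequence="".join(parts))

    prots = [synth_protein("SYN1"), synth_protein("SYN2")]
    entries = prots + [p.reversed() for p in prots]
    params = DigestParams(max_missed_cleavages=2)
    peps = [p for e in entries for p in digest(e, params)]
    cands = enumerate_candidates(peps, peps, get_linker("BS3"))
    targets = [c for c in cands if not c.is_decoy]
    chosen = list(rng.choice(len(targets), size=40, replace=False))
    rows = []
    planted = []
    for idx in chosen:
        c = targets[idx]
        planted.append(c)
        rt = rng.uniform(5, 90)
        for z in (2, 3):
            jit = lambda: 1.0 + rng.normal(0, 1.0) * 1e-6
            inten = rng.uniform(1e5, 1e6)
            rows.append((c.mz(z) * jit(), z, inten, rt))
            rows.append((c.mz(z, heavy=True) * jit(), z, inten, rt))
    n_decoy_peaks = int(0.1 * len(rows))
    mzs = [r[0] for r in rows]
    for _ in range(n_decoy_peaks):
        rows.append(
            (rng.uniform(min(mzs), max(mzs)), int(rng.integers(2, 4)),
             rng.uniform(1e5, 1e6), rng.uniform(5, 90))
        )
    peaks = pd.DataFrame(rows, columns=["mz", "z", "intensity", "rt_min"])
    return peaks, cands, planted


class TestFdr:
    def test_planted_recall_and_fdr_on_decoy_fixture(self):
        peaks, cands, planted = _target_decoy_fixture()
        hits = match_doublets(peaks, cands)
        accepted = filter_fdr(hits, fdr_max=0.05, final_ppm=15.0)
        key = lambda c: (c.peptide_a.sequence, c.peptide_b.sequence)
        got = {key(h.candidate) for h in accepted}
        want = {key(c) for c in planted}
        recall = len(got & want) / len(want)
        assert recall >= 0.90
        # decoy-estimated FDR at the acceptance threshold
        assert all(h.qvalue <= 0.05 for h in accepted)
        assert not any(h.is_decoy for h in accepted)
        # wrong-pair assignments (isobaric target pairs, indistinguishable
        # at the MS1 level) stay a small minority
        assert len(got - want) <= 0.1 * len(got)

    def test_no_decoys_all_targets_pass_then_ppm_filter(self):
        peaks, cands, planted = _planted_fixture(jitter_sd=0.0, decoys=0, seed=5)
        hits = match_doublets(peaks, cands)
        accepted = filter_fdr(hits, fdr_max=0.05, final_ppm=2.0)
        assert len(accepted) == len(hits)  # 0 ppm: everything survives

    def test_final_ppm_filter_is_unconditional(self):
        peaks, cands, planted = _planted_fixture(jitter_sd=0.0, decoys=0, seed=5)
        hits = match_doublets(peaks, cands)
        # push one hit's error to 2.5 ppm: it must disappear even at FDR 0
        import dataclasses

        bad = dataclasses.replace(hits[0], ppm_error=2.5, score=-2.5)
        accepted = filter_fdr([bad] + hits[1:], fdr_max=0.05, final_ppm=2.0)
        assert all(abs(h.ppm_error) < 2.0 for h in accepted)
        assert len(accepted) == len(hits) - 1

    def test_zero_target_hits_empty_output(self):
        assert filter_fdr([], fdr_max=0.05) == []

    def test_qvalues_monotone_as_score_decreases(self):
        peaks, cands, planted = _target_decoy_fixture()
        hits = match_doublets(peaks, cands)
        accepted = filter_fdr(hits, fdr_max=1.0, final_ppm=15.0)
        ordered = sorted(accepted, key=lambda h: -h.score)
        qs = [h.qvalue for h in ordered]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))

    def test_doublet_requirement_reduces_hits_vs_light_only(self):
        peaks, cands, planted = _target_decoy_fixture()
        hits = match_doublets(peaks, cands)
        # light-only count: candidates with any peak within tolerance of the
        # light m/z, ignoring the heavy requirement
        light_only = 0
        for c in cands:
            for z in (2, 3):
                mz = c.mz(z)
                sub = peaks[peaks.z == z]
                if (abs(sub.mz - mz) / mz * 1e6 <= 15.0).any():
                    light_only += 1
                    break
        assert len(hits) < light_only


class TestReport:
    def test_duplicate_hits_collapse_with_multiplicity(self):
        peaks, cands, planted = _planted_fixture(jitter_sd=0.0, decoys=0, seed=5,
                                                 charges=(2, 3))
        hits = match_doublets(peaks, cands)
        table = report_links(hits)
        # every pair was planted at two charges -> multiplicity 2, one row
        assert (table.multiplicity >= 2).all()
        dup = table[(table.peptide_a == "MEQEKIDK") & (table.peptide_b == "YHPDKNK")]
        if dup.empty:
            dup = table[(table.peptide_b == "MEQEKIDK") & (table.peptide_a == "YHPDKNK")]
        assert len(dup) == 1

    def test_zero_hits_empty_table_with_header(self):
        table = report_links([])
        assert len(table) == 0
        assert list(table.columns[:6]) == [
            "peptide_a", "peptide_b", "protein_a", "pos_a", "protein_b", "pos_b",
        ]

    def test_intra_protein_pairs_tagged(self):
        a = mk_pep("DYYKVLGISK", "DNJ-13", 4)
        b = mk_pep("GATDDEIKK", "DNJ-13", 14)
        cand = enumerate_candidates([a], [b], get_linker("DSSG"))[0]
        peaks = pd.DataFrame(
            {
                "mz": [cand.mz(2), cand.mz(2, heavy=True)],
                "z": [2, 2],
                "intensity": [1e6, 1e6],
                "rt_min": [30.0, 30.0],
            }
        )
        hits = match_doublets(peaks, [cand])
        table = report_links(hits)
        assert (table.link_type == "intra").all()

    def test_unknown_protein_rejected(self):
        a = mk_pep("GTTSKK", "CDC-37", 56)
        b = mk_pep("EAGAENKFK", "DNJ-13", 38)
        cand = enumerate_candidates([a], [b], get_linker("BS3"))[0]
        peaks = pd.DataFrame(
            {"mz": [cand.mz(2), cand.mz(2, heavy=True)], "z": [2, 2],
             "intensity": [1e6, 1e6], "rt_min": [30.0, 30.0]}
        )
        hits = match_doublets(peaks, [cand])
        with pytest.raises(ValueError, match="unknown protein"):
            report_links(hits, proteins=[ProteinEntry(id="OTHER", sequence="MK")])


def test_end_to_end_search_on_synthetic_proteins(tmp_path):
    """Full search() round trip: plant doublets for candidates digested from
    synthetic proteins, recover them through FDR filtering."""
    peaks, cands, planted = _target_decoy_fixture(seed=9)
    prot_ids = {c.peptide_a.protein_id for c in planted} | {
        c.peptide_b.protein_id for c in planted
    }
    assert all(not pid.startswith("DECOY_") for pid in prot_ids)
    hits = match_doublets(peaks, cands)
    accepted = filter_fdr(hits, fdr_max=0.05, final_ppm=15.0)
    table = report_links(accepted)
    assert len(table) >= 0.9 * len({(c.peptide_a.sequence, c.peptide_b.sequence)
                                    for c in planted})
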
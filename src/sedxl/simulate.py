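"""Synthetic-data generation: reacting sedimentation systems, titration
series, MS1 peak lists with planted isotope doublets, and toy two-chain
structures with planted crosslink distances.

Every generator is seeded and byte-deterministic: identical seeds give
identical files. The study conditions emulated by the defaults are a
fluorescence-detected SV run at 42,000 rpm and 20 C with a 300 nM labeled
receptor and 2 uM partner, a 0-10 uM titration at 100 nM receptor, and
1:1 light/heavy isotope-coded crosslinker mixes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import equilibrate
from .constants import PROTON_MASS
from .digest import CANONICAL, peptide_mass
from .lamm import CellGeometry, NoiseModel, ScanSchedule, SpeciesParams, solve_lamm
from .linkers import get_linker
from .scans import ScanSet

__all__ = [
    "BindingSystem",
    "equilibrate_then_simulate",
    "make_titration",
    "PeakListSpec",
    "gen_peaklist",
    "write_peaklist",
    "ToyComplexSpec",
    "InfeasibleConstraintError",
    "gen_toy_complex",
]


@dataclass
class BindingSystem:
    """A 1:1 reacting pair A + B <-> AB; B may itself be a dimer treated as
    one entity. The complex is assumed kinetically stable on the run
    timescale (slow exchange), so the equilibrium loadings sediment as
    independent species with distinct s-values."""

    a_total: float  # molar
    b_total: float  # molar
    kd: float  # molar
    species_free_a: SpeciesParams
    species_free_b: SpeciesParams
    species_complex: SpeciesParams

    def __post_init__(self) -> None:
        if self.a_total < 0 or self.b_total < 0:
            raise ValueError("totals must be >= 0")
        if self.kd <= 0:
            raise ValueError("kd must be positive")

    def loadings(self) -> tuple[float, float, float]:
        return equilibrate(self.a_total, self.b_total, self.kd)


def equilibrate_then_simulate(
    system: BindingSystem,
    geometry: CellGeometry,
    schedule: ScanSchedule,
    channel: str = "fluorescence",
    noise: NoiseModel | None = None,
    **solve_kwargs,
) -> ScanSet:
    """Mass-action equilibrium, then slow-exchange sedimentation of the
    three species (free A, free B, complex) at their equilibrium loadings."""
    free_a, free_b, ab = system.loadings()
    return solve_lamm(
        [system.species_free_a, system.species_free_b, system.species_complex],
        geometry,
        schedule,
        loading=[free_a, free_b, ab],
        channel=channel,
        noise=noise,
        **solve_kwargs,
    )


def make_titration(
    system: BindingSystem,
    b_concentrations,
    geometry: CellGeometry,
    schedule: ScanSchedule,
    channel: str = "fluorescence",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[float, ScanSet]:
    """One ScanSet per ligand concentration, shared geometry and schedule.

    The per-point noise seed is derived deterministically from ``seed`` and
    the point index, so the whole series is reproducible bit-for-bit.
    """
    concs = list(b_concentrations)
    if not concs:
        raise ValueError("empty titration series")
    if any(c < 0 for c in concs) or sorted(concs) != concs:
        raise ValueError("concentrations must be non-negative and sorted")
    out = {}
    for i, b in enumerate(concs):
        sys_i = BindingSystem(
            a_total=system.a_total,
            b_total=b,
            kd=system.kd,
            species_free_a=system.species_free_a,
            species_free_b=system.species_free_b,
            species_complex=system.species_complex,
        )
        noise = NoiseModel(gaussian_sd=noise_sd, seed=seed * 10007 + i) if noise_sd else None
        out[b] = equilibrate_then_simulate(sys_i, geometry, schedule, channel, noise)
    return out


# ---------------------------------------------------------------------------
# MS1 peak lists with planted isotope-coded doublets
# ---------------------------------------------------------------------------


@dataclass
class PeakListSpec:
    """Recipe for a synthetic MS1 peak list.

    ``pairs`` are (peptide_a, peptide_b, linker_name) tuples; each planted
    pair produces one light and one heavy peak per charge state, with ppm
    jitter and a shared retention time. ``decoy_peak_count`` unassignable
    singleton peaks are appended.
    """

    pairs: list
    charges: tuple = (2, 3, 4)
    ppm_jitter_sd: float = 0.0
    heavy_light_ratio: float = 1.0
    decoy_peak_count: int = 0
    seed: int = 0
    gradient_min: float = 95.0

    def __post_init__(self) -> None:
        if not set(self.charges) <= set(range(1, 7)):
            raise ValueError("charges must be within 1..6")
        if self.ppm_jitter_sd < 0:
            raise ValueError("ppm_jitter_sd must be >= 0")


def gen_peaklist(spec: PeakListSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (peak list, ground truth) for planted crosslink doublets.

    Peak list columns: mz, z, intensity, rt_min. Ground-truth columns:
    peptide_a, peptide_b, linker, charge, mz_light, mz_heavy, rt_min
    (theoretical positions, before jitter).
    """
    rng = np.random.default_rng(spec.seed)
    peaks = []
    truth = []
    for pep_a, pep_b, linker_name in spec.pairs:
        for pep in (pep_a, pep_b):
            bad = set(pep) - CANONICAL
            if bad:
                raise ValueError(f"non-canonical residues in {pep!r}: {sorted(bad)}")
        linker = get_linker(linker_name)
        light = peptide_mass(pep_a) + peptide_mass(pep_b) + linker.bridge_mass_light
        heavy = light + linker.heavy_delta
        rt = rng.uniform(2.0, spec.gradient_min)
        for z in spec.charges:
            mz_l = (light + z * PROTON_MASS) / z
            mz_h = (heavy + z * PROTON_MASS) / z
            jit_l = rng.normal(0.0, spec.ppm_jitter_sd) * 1e-6
            jit_h = rng.normal(0.0, spec.ppm_jitter_sd) * 1e-6
            base = rng.uniform(5e5, 5e6)
            peaks.append((mz_l * (1 + jit_l), z, base, rt))
            peaks.append((mz_h * (1 + jit_h), z, base * spec.heavy_light_ratio, rt))
            truth.append((pep_a, pep_b, linker_name, z, mz_l, mz_h, rt))
    if spec.pairs:
        lo = min(p[0] for p in peaks) * 0.9
        hi = max(p[0] for p in peaks) * 1.1
    else:
        lo, hi = 350.0, 1400.0
    for _ in range(spec.decoy_peak_count):
        peaks.append(
            (
                rng.uniform(lo, hi),
                int(rng.integers(1, 7)),
                rng.uniform(5e5, 5e6),
                rng.uniform(2.0, spec.gradient_min),
            )
        )
    peak_df = pd.DataFrame(peaks, columns=["mz", "z", "intensity", "rt_min"])
    truth_df = pd.DataFrame(
        truth,
        columns=["peptide_a", "peptide_b", "linker", "charge", "mz_light", "mz_heavy", "rt_min"],
    )
    return peak_df, truth_df


def write_peaklist(peaks: pd.DataFrame, path: str | Path) -> Path:
    """Write a peak list as TSV with fixed formatting (byte-deterministic)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("mz\tz\tintensity\trt_min\n")
        for row in peaks.itertuples(index=False):
            fh.write(f"{row.mz:.6f}\t{int(row.z)}\t{row.intensity:.1f}\t{row.rt_min:.3f}\n")
    return path


# ---------------------------------------------------------------------------
# Toy two-chain structures with planted distances
# ---------------------------------------------------------------------------


class InfeasibleConstraintError(ValueError):
    """Planted distance constraints cannot be realized; names the pair."""


@dataclass
class ToyComplexSpec:
    """Two Calpha-only pseudo-chains (A, B) with planted inter-chain
    distances: ``planted_pairs`` is a list of
    (chain_a, res_a, chain_b, res_b, distance_A)."""

    chain_lengths: tuple = (60, 60)
    planted_pairs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for ca, ra, cb, rb, d in self.planted_pairs:
            n = {"A": self.chain_lengths[0], "B": self.chain_lengths[1]}
            if not (1 <= ra <= n[ca]) or not (1 <= rb <= n[cb]):
                raise ValueError(f"planted pair ({ca}{ra}, {cb}{rb}) outside chain lengths")
            if d <= 0:
                raise ValueError("planted distances must be positive")


def _pdb_atom_line(serial: int, chain: str, resnum: int, xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
    )


def gen_toy_complex(
    spec: ToyComplexSpec, pdb_path: str | Path, truth_path: str | Path | None = None
) -> tuple[Path, pd.DataFrame]:
    """Build a two-chain Calpha-only pseudo-structure realizing each planted
    pair distance to within 0.01 A, write it as PDB, and return the truth
    table of realized distances.

    Chains start as straight 3.8 A-spaced strands far apart; the chain-B
    residue of each planted pair is then moved onto the sphere (or sphere
    intersection, for residues constrained by several pairs) that realizes
    the requested distance, with seeded random orientation. An inconsistent
    constraint set raises :class:`InfeasibleConstraintError` naming the
    offending pair.
    """
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.chain_lengths
    spacing = 3.8
    coords = {
        "A": {i + 1: np.array([spacing * i, 0.0, 0.0]) for i in range(n_a)},
        "B": {i + 1: np.array([spacing * i, 120.0, 0.0]) for i in range(n_b)},
    }

    # group constraints by the residue that will be moved (prefer chain B)
    by_target: dict[tuple, list] = {}
    for ca, ra, cb, rb, d in spec.planted_pairs:
        target, anchor = ((cb, rb), (ca, ra)) if cb == "B" else ((ca, ra), (cb, rb))
        by_target.setdefault(target, []).append((anchor, float(d), (ca, ra, cb, rb, d)))

    for (tc, tr), cons in by_target.items():
        anchors = np.array([coords[a[0]][a[1]] for a, _, _ in cons])
        dists = np.array([d for _, d, _ in cons])
        if len(cons) == 1:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            pos = anchors[0] + dists[0] * u
        else:
            from scipy.optimize import least_squares

            def resid(x):
                return np.linalg.norm(anchors - x, axis=1) - dists

            best = None
            for _ in range(8):
                x0 = anchors.mean(axis=0) + rng.standard_normal(3) * dists.mean()
                sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
                if best is None or sol.cost < best.cost:
                    best = sol
            pos = best.x
            if np.abs(resid(pos)).max() > 0.005:
                bad = cons[int(np.argmax(np.abs(resid(pos))))][2]
                raise InfeasibleConstraintError(
                    f"cannot realize planted pair {bad} together with the other "
                    f"constraints on {tc}{tr}"
                )
        coords[tc][tr] = pos

    pdb_path = Path(pdb_path)
    lines = []
    serial = 1
    for chain in ("A", "B"):
        for resnum in sorted(coords[chain]):
            lines.append(_pdb_atom_line(serial, chain, resnum, coords[chain][resnum]))
            serial += 1
        lines.append(f"TER   {serial:5d}      ALA {chain}{max(coords[chain]):4d}")
        serial += 1
    lines.append("END")
    pdb_path.write_text("\n".join(lines) + "\n")

    rows = []
    for ca, ra, cb, rb, d in spec.planted_pairs:
        realized = float(np.linalg.norm(coords[ca][ra] - coords[cb][rb]))
        rows.append(
            {
                "chain_a": ca,
                "res_a": ra,
                "chain_b": cb,
                "res_b": rb,
                "requested_A": d,
                "realized_A": realized,
            }
        )
    truth = pd.DataFrame(
        rows, columns=["chain_a", "res_a", "chain_b", "res_b", "requested_A", "realized_A"]
    )
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False, float_format="%.4f")
    return pdb_path, truth
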
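"""High-level analysis workflows chaining simulation and recovery stages.

These convenience functions wire the common validation loops together:
simulate an ideal species (or mixture), run the dc/dt stage, and return the
fitted peaks; or simulate one species and estimate its molar mass through
the (s, f/f0) grid decomposition. They are also the self-consistency
harness: a correctly implemented transport solver and analysis stage must
return the parameters the simulation was given.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_FF0, DEFAULT_VBAR
from .dcdt import PeakFit, dcdt_curves, fit_peaks, gs_distribution
from .hydro import GridFitResult, grid_fit, mw_from_sD, s_from_mass_ff0
from .lamm import CellGeometry, NoiseModel, ScanSchedule, SpeciesParams, solve_lamm
from .scans import ScanSet

__all__ = [
    "simulate_single_species",
    "recover_peaks",
    "recover_single_species_peak",
    "estimate_mass_by_gridfit",
]

#: default mid-late scan window (fractions of the scan list) for dc/dt;
#: early pairs are s*-compressed, late pairs see back-diffusion
DEFAULT_WINDOW_FRAC = (0.5, 0.9)


def simulate_single_species(
    s: float,
    ff0: float = DEFAULT_FF0,
    vbar: float = DEFAULT_VBAR,
    geometry: CellGeometry | None = None,
    n_scans: int = 50,
    channel: str = "fluorescence",
    loading: float = 1.0,
    noise: NoiseModel | None = None,
) -> ScanSet:
    """Simulate one ideal species at sedimentation coefficient ``s``
    (Svedberg), D from the Svedberg relation at the given frictional ratio,
    with a scan schedule covering the species' own boundary transit."""
    geometry = geometry or CellGeometry()
    schedule = ScanSchedule.for_species(s, geometry, n_scans=n_scans)
    sp = SpeciesParams(name=f"{s:.2f}S", s=s, ff0=ff0, vbar=vbar, signal={channel: 1.0})
    return solve_lamm([sp], geometry, schedule, [loading], channel=channel, noise=noise)


def recover_peaks(
    scans: ScanSet,
    n_peaks: int | None = None,
    window_frac: tuple[float, float] = DEFAULT_WINDOW_FRAC,
    normalization: str = "area",
    fit_seed: int = 0,
) -> list[PeakFit]:
    """Run the dc/dt stage (difference, transform, average, Gaussian fit) on
    a scan set over a fractional mid-run scan window."""
    lo = int(window_frac[0] * (scans.n_scans - 1))
    hi = int(window_frac[1] * (scans.n_scans - 1))
    window = (lo, hi)
    curves = dcdt_curves(scans, scan_range=window)
    gs = gs_distribution(curves, scans, scan_range=window, normalization=normalization)
    return fit_peaks(gs, n_peaks=n_peaks, seed=fit_seed)


def recover_single_species_peak(
    s: float,
    ff0: float = DEFAULT_FF0,
    geometry: CellGeometry | None = None,
    n_scans: int = 50,
    fit_seed: int = 0,
) -> float:
    """Simulate a single ideal species and return the fitted g(s*) peak
    center in Svedberg (area normalization, single-Gaussian fit)."""
    scans = simulate_single_species(s, ff0=ff0, geometry=geometry, n_scans=n_scans)
    peaks = recover_peaks(scans, n_peaks=1, fit_seed=fit_seed)
    return peaks[-1].center_s


def estimate_mass_by_gridfit(
    mass_g_mol: float,
    ff0: float = DEFAULT_FF0,
    vbar: float = DEFAULT_VBAR,
    s_range: tuple[float, float] = (3.0, 9.0),
    n_s: int = 25,
    ff0_values: tuple[float, ...] = (1.2, 1.4, 1.6, 1.8),
    geometry: CellGeometry | None = None,
    n_scans: int = 30,
    n_radial_points: int = 240,
) -> tuple[float, GridFitResult]:
    """Simulate a species of known molar mass, decompose the scans over an
    (s, f/f0) grid by NNLS, and return the dominant node's Svedberg-equation
    mass estimate (g/mol) along with the full fit."""
    geometry = geometry or CellGeometry()
    s_true = s_from_mass_ff0(mass_g_mol, ff0, vbar)
    schedule = ScanSchedule.for_species(
        s_true, geometry, n_scans=n_scans, n_radial_points=n_radial_points
    )
    sp = SpeciesParams(
        name="sample", s=s_true, M=mass_g_mol, vbar=vbar, signal={"absorbance": 1.0}
    )
    scans = solve_lamm([sp], geometry, schedule, [1.0], channel="absorbance")
    res = grid_fit(
        scans, np.linspace(*s_range, n_s), list(ff0_values), geometry, vbar=vbar
    )
    dom = res.dominant
    m_est = mw_from_sD(dom["s"], dom["D"], vbar)
    return m_est, res
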
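"""Hydrodynamic parameter relations and a simplified s x f/f0 grid fit.

The Svedberg equation links the sedimentation coefficient s, the diffusion
coefficient D and the molar mass M of an ideal species:

    M = s R T / (D (1 - vbar * rho))

For a species of given mass and frictional ratio f/f0, the translational
friction coefficient is f = (f/f0) * 6 pi eta R0, where R0 is the radius of
the anhydrous sphere of equal volume. These relations let any two of
(s, D, M, f/f0) fix the others, which is the basis of the two-dimensional
(s, f/f0) grid decomposition implemented in :func:`grid_fit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DEFAULT_VBAR,
    N_AVOGADRO,
    R_GAS,
    SVEDBERG,
    WATER_DENSITY_20C,
    WATER_VISCOSITY_20C,
)

__all__ = [
    "SolventContext",
    "mw_from_sD",
    "d_from_sM",
    "mass_from_s_ff0",
    "d_from_s_ff0",
    "s_from_mass_ff0",
    "GridFitResult",
    "grid_fit",
]


@dataclass(frozen=True)
class SolventContext:
    """Solvent conditions entering the Svedberg relation.

    Defaults are water at 20 degrees C; no s20,w correction is performed,
    raw experimental s-values are used throughout.
    """

    temperature_K: float = 293.15
    density_g_per_mL: float = WATER_DENSITY_20C
    viscosity_cP: float = WATER_VISCOSITY_20C * 100.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if self.density_g_per_mL <= 0:
            raise ValueError("density must be positive")

    @property
    def viscosity_poise(self) -> float:
        return self.viscosity_cP / 100.0


def _buoyancy(vbar: float, ctx: SolventContext) -> float:
    b = 1.0 - vbar * ctx.density_g_per_mL
    if b <= 0:
        raise ValueError(
            f"vbar*rho = {vbar * ctx.density_g_per_mL:.4f} >= 1: species floats; "
            "the Svedberg relation is undefined"
        )
    return b


def mw_from_sD(
    s: float, D: float, vbar: float = DEFAULT_VBAR, ctx: SolventContext | None = None
) -> float:
    """Molar mass (g/mol) from the Svedberg equation, M = sRT / (D(1-vbar*rho)).

    Parameters
    ----------
    s : sedimentation coefficient in Svedberg (1 S = 1e-13 s).
    D : diffusion coefficient in cm^2/s.
    """
    ctx = ctx or SolventContext()
    if D <= 0:
        raise ValueError("D must be positive")
    return (s * SVEDBERG) * R_GAS * ctx.temperature_K / (D * _buoyancy(vbar, ctx))


def d_from_sM(
    s: float, M: float, vbar: float = DEFAULT_VBAR, ctx: SolventContext | None = None
) -> float:
    """Diffusion coefficient (cm^2/s) from s (Svedberg) and molar mass (g/mol).

    Exact inverse of :func:`mw_from_sD`.
    """
    ctx = ctx or SolventContext()
    if M <= 0:
        raise ValueError("M must be positive")
    return (s * SVEDBERG) * R_GAS * ctx.temperature_K / (M * _buoyancy(vbar, ctx))


def _stokes_prefactor(ff0: float, vbar: float, ctx: SolventContext) -> float:
    """f = ff0 * 6 pi eta * (3 M vbar / (4 pi N_A))^(1/3) == prefactor * M^(1/3)."""
    if ff0 < 1.0:
        raise ValueError("frictional ratio f/f0 must be >= 1")
    return ff0 * 6.0 * math.pi * ctx.viscosity_poise * (
        3.0 * vbar / (4.0 * math.pi * N_AVOGADRO)
    ) ** (1.0 / 3.0)


def mass_from_s_ff0(
    s: float, ff0: float, vbar: float = DEFAULT_VBAR, ctx: SolventContext | None = None
) -> float:
    """Molar mass (g/mol) of the species with sedimentation coefficient ``s``
    (Svedberg) and frictional ratio ``ff0``.

    From s = M (1 - vbar rho) / (N_A f) with f = prefactor * M^(1/3):
    M^(2/3) = s N_A * prefactor / (1 - vbar rho).
    """
    ctx = ctx or SolventContext()
    b = _buoyancy(vbar, ctx)
    pref = _stokes_prefactor(ff0, vbar, ctx)
    m23 = (s * SVEDBERG) * N_AVOGADRO * pref / b
    return m23**1.5


def s_from_mass_ff0(
    M: float, ff0: float, vbar: float = DEFAULT_VBAR, ctx: SolventContext | None = None
) -> float:
    """Sedimentation coefficient (Svedberg) of a species of mass M (g/mol)
    and frictional ratio ``ff0``. Inverse of :func:`mass_from_s_ff0`."""
    ctx = ctx or SolventContext()
    b = _buoyancy(vbar, ctx)
    pref = _stokes_prefactor(ff0, vbar, ctx)
    f = pref * M ** (1.0 / 3.0)
    return M * b / (N_AVOGADRO * f) / SVEDBERG


def d_from_s_ff0(
    s: float, ff0: float, vbar: float = DEFAULT_VBAR, ctx: SolventContext | None = None
) -> float:
    """Diffusion coefficient (cm^2/s) for a grid node (s in Svedberg, f/f0)."""
    M = mass_from_s_ff0(s, ff0, vbar, ctx)
    return d_from_sM(s, M, vbar, ctx)


# ---------------------------------------------------------------------------
# s x f/f0 grid decomposition (simplified two-dimensional spectrum analysis)
# ---------------------------------------------------------------------------


@dataclass
class GridFitResult:
    """Result of the non-negative least-squares decomposition of a scan set
    over a fixed grid of ideal species.

    ``species`` holds one row per grid node whose weight is at least 1% of
    the total, with the node's (s, f/f0) and derived (D, M).
    """

    grid: list  # list of (s_svedberg, ff0)
    weights: np.ndarray
    rmse: float
    vbar: float
    species: "pd.DataFrame" = field(default=None)  # type: ignore[name-defined]

    @property
    def dominant(self):
        """Row of ``species`` carrying the largest weight."""
        return self.species.loc[self.species["weight"].idxmax()]

    def summary(self) -> str:
        lines = [
            "s x f/f0 grid fit (NNLS)",
            f"  grid nodes : {len(self.grid)}",
            f"  rmse       : {self.rmse:.4g}",
            "  detected species (weight >= 1% of total):",
        ]
        for _, row in self.species.iterrows():
            lines.append(
                f"    s = {row['s']:5.2f} S  f/f0 = {row['ff0']:.2f}  "
                f"M = {row['M'] / 1000:7.1f} kDa  D = {row['D']:.3e} cm^2/s  "
                f"weight = {row['frac']:.1%}"
            )
        return "\n".join(lines)


def grid_fit(
    scans,
    s_values,
    ff0_values,
    geometry,
    schedule=None,
    vbar: float = DEFAULT_VBAR,
    ctx: SolventContext | None = None,
    min_weight_frac: float = 0.01,
) -> GridFitResult:
    """Decompose a scan set over a grid of simulated ideal species.

    Each grid node (s, f/f0) is simulated with the same radial grid, rotor
    speed and scan times as the data (unit loading), and the observed scans
    are fitted jointly as a non-negative superposition of the node profiles.
    Nodes carrying at least ``min_weight_frac`` of the total weight are
    reported with their Svedberg-derived D and M.

    Parameters
    ----------
    scans : ScanSet
        The data to decompose.
    s_values, ff0_values : sequences defining the grid (s in Svedberg).
    geometry : CellGeometry used to acquire/simulate the data.
    schedule : optional ScanSchedule; by default the basis is simulated at
        exactly the data's scan times.
    """
    import pandas as pd
    from scipy.optimize import nnls

    from .lamm import ScanSchedule, SpeciesParams, solve_lamm

    ctx = ctx or SolventContext()
    grid = [(float(s), float(f)) for s in s_values for f in ff0_values]
    if len(grid) > 200:
        raise ValueError(f"grid has {len(grid)} nodes; limit is 200")
    if len(set(grid)) != len(grid):
        raise ValueError("duplicate grid nodes")

    times = np.asarray(scans.times_s, dtype=float)
    if schedule is None:
        schedule = ScanSchedule.from_times(times, n_radial_points=len(scans.radii_cm))

    basis = np.empty((scans.signals.size, len(grid)))
    for j, (s, ff0) in enumerate(grid):
        D = d_from_s_ff0(s, ff0, vbar, ctx)
        sp = SpeciesParams(name=f"node_{j}", s=s, D=D, vbar=vbar, signal={scans.channel: 1.0})
        sim = solve_lamm([sp], geometry, schedule, loading=[1.0], channel=scans.channel)
        # basis simulated on the same radial grid; interpolate if it differs
        if len(sim.radii_cm) == len(scans.radii_cm) and np.allclose(
            sim.radii_cm, scans.radii_cm
        ):
            basis[:, j] = sim.signals.ravel()
        else:
            prof = np.vstack(
                [np.interp(scans.radii_cm, sim.radii_cm, row) for row in sim.signals]
            )
            basis[:, j] = prof.ravel()

    y = scans.signals.ravel()
    w, rnorm = nnls(basis, y)
    rmse = rnorm / math.sqrt(len(y))

    total = w.sum()
    rows = []
    if total > 0:
        for j, (s, ff0) in enumerate(grid):
            if w[j] >= min_weight_frac * total:
                D = d_from_s_ff0(s, ff0, vbar, ctx)
                M = mw_from_sD(s, D, vbar, ctx)
                rows.append(
                    {"s": s, "ff0": ff0, "D": D, "M": M, "weight": w[j], "frac": w[j] / total}
                )
    species = pd.DataFrame(rows, columns=["s", "ff0", "D", "M", "weight", "frac"])
    return GridFitResult(grid=grid, weights=w, rmse=rmse, vbar=vbar, species=species)
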
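"""Finite-volume Lamm-equation solver for sector-shaped ultracentrifuge cells.

The Lamm equation describes radial transport of a sedimenting, diffusing
species at angular velocity omega:

    dc/dt = (1/r) d/dr [ r ( D dc/dr - s omega^2 r c ) ]

with zero total flux at the meniscus and cell bottom (reflective ends). The
solver discretizes the conservative form on a uniform radial grid of cell
volumes, using Scharfetter-Gummel exponential fitting for the combined
advective/diffusive face flux (robust at any cell Peclet number) and
Crank-Nicolson time stepping with the step bounded by a Courant condition.
Because face fluxes telescope, the sector-weighted total mass
sum_i c_i r_i dr is conserved to round-off.

Species sediment independently; a detection channel's signal is the
superposition sum_k coeff_k(channel) * c_k(r, t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix, identity
from scipy.sparse.linalg import splu

from .constants import DEFAULT_FF0, DEFAULT_VBAR, SVEDBERG, rpm_to_omega
from .hydro import SolventContext, d_from_s_ff0, d_from_sM
from .scans import ScanSet

__all__ = [
    "SpeciesParams",
    "CellGeometry",
    "ScanSchedule",
    "NoiseModel",
    "LammInstabilityError",
    "solve_lamm",
]


class LammInstabilityError(RuntimeError):
    """Raised when the transport solve produces non-finite concentrations."""


@dataclass
class SpeciesParams:
    """One ideal sedimenting species.

    The diffusion coefficient may be given directly (``D``, cm^2/s) or
    derived from the Svedberg relation via molar mass ``M`` (g/mol) or the
    frictional ratio ``ff0``; precedence is D, then M, then ff0 (defaulting
    to 1.4 for a moderately elongated globular protein).

    ``signal`` maps a channel name to the species' signal coefficient in
    that channel (signal units per molar concentration). A fluorescence
    channel typically carries nonzero coefficients only for species
    containing the labeled protomer.
    """

    name: str
    s: float  # Svedberg
    D: float | None = None  # cm^2/s
    M: float | None = None  # g/mol
    ff0: float | None = None
    vbar: float = DEFAULT_VBAR
    signal: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be positive")
        if not 0.5 < self.vbar < 0.9:
            raise ValueError("vbar outside the plausible (0.5, 0.9) mL/g range")
        if any(v < 0 for v in self.signal.values()):
            raise ValueError("signal coefficients must be >= 0")

    def resolve_D(self, ctx: SolventContext | None = None) -> float:
        if self.D is not None:
            return self.D
        if self.M is not None:
            return d_from_sM(self.s, self.M, self.vbar, ctx)
        ff0 = self.ff0 if self.ff0 is not None else DEFAULT_FF0
        return d_from_s_ff0(self.s, ff0, self.vbar, ctx)

    def coeff(self, channel: str) -> float:
        return float(self.signal.get(channel, 0.0))


@dataclass(frozen=True)
class CellGeometry:
    """Sector cell geometry and run conditions."""

    meniscus_cm: float = 6.0
    bottom_cm: float = 7.2
    rpm: float = 42000.0
    temperature_C: float = 20.0

    def __post_init__(self) -> None:
        if not (5.8 <= self.meniscus_cm < self.bottom_cm <= 7.3):
            raise ValueError("require 5.8 <= meniscus < bottom <= 7.3 cm")
        if self.rpm <= 0:
            raise ValueError("rpm must be positive")

    @property
    def omega(self) -> float:
        return rpm_to_omega(self.rpm)

    @property
    def omega2(self) -> float:
        return self.omega**2


@dataclass
class ScanSchedule:
    """When scans are acquired and how finely the cell is gridded."""

    first_time_s: float = 600.0
    interval_s: float = 300.0
    n_scans: int = 40
    n_radial_points: int = 400
    explicit_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.explicit_times is None:
            if min(self.first_time_s, self.interval_s) <= 0 or self.n_radial_points <= 0:
                raise ValueError("schedule times and grid size must be positive")
            if self.n_scans < 2:
                raise ValueError("need at least 2 scans")

    @classmethod
    def from_times(cls, times_s, n_radial_points: int = 400) -> "ScanSchedule":
        times = np.asarray(times_s, dtype=float)
        return cls(
            first_time_s=float(times[0]) if times[0] > 0 else 1.0,
            interval_s=1.0,
            n_scans=len(times),
            n_radial_points=n_radial_points,
            explicit_times=times,
        )

    @classmethod
    def for_species(
        cls,
        s_svedberg: float,
        geometry: CellGeometry,
        n_scans: int = 40,
        n_radial_points: int = 400,
        start_frac: float = 0.12,
        end_frac: float = 0.70,
    ) -> "ScanSchedule":
        """Schedule covering the run window in which the boundary midpoint of
        an ``s_svedberg`` species travels from ``start_frac`` to ``end_frac``
        of the column height (by ln-radius fraction)."""
        span = math.log(geometry.bottom_cm / geometry.meniscus_cm)
        rate = s_svedberg * SVEDBERG * geometry.omega2
        t0 = start_frac * span / rate
        t1 = end_frac * span / rate
        dt = (t1 - t0) / (n_scans - 1)
        return cls(
            first_time_s=t0, interval_s=dt, n_scans=n_scans, n_radial_points=n_radial_points
        )

    @property
    def times(self) -> np.ndarray:
        if self.explicit_times is not None:
            return np.asarray(self.explicit_times, dtype=float)
        return self.first_time_s + self.interval_s * np.arange(self.n_scans)


@dataclass
class NoiseModel:
    """Additive Gaussian noise and constant baseline; seeded, deterministic."""

    gaussian_sd: float = 0.0
    baseline_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")

    def apply(self, signals: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return signals + self.baseline_offset + rng.normal(0.0, self.gaussian_sd, signals.shape)


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the Scharfetter-Gummel weighting function."""
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - x[small] / 2.0
    xs = x[~small]
    # guard overflow for strongly advective faces: B(x) -> 0 for x >> 0,
    # B(x) -> -x for x << 0
    with np.errstate(over="ignore"):
        out[~small] = np.where(
            xs > 500,
            0.0,
            np.where(xs < -500, -xs, xs / np.expm1(np.clip(xs, -500, 500))),
        )
    return out


def _transport_matrix(
    r_centers: np.ndarray, dr: float, s_sec: float, D: float, omega2: float
) -> csc_matrix:
    """Tridiagonal dc/dt = A c for one species (reflective ends)."""
    n = len(r_centers)
    r_faces = np.concatenate(([r_centers[0] - dr / 2], r_centers + dr / 2))
    # interior faces 1..n-1
    rf = r_faces[1:-1]
    v = s_sec * omega2 * rf  # outward advection velocity at each face
    P = v * dr / D
    bm = _bernoulli(-P)  # weight on the inner (left) cell
    bp = _bernoulli(P)  # weight on the outer (right) cell
    # flux through face k (k=1..n-1): F_k = (D/dr) * (bm_k * c_{k-1} - bp_k * c_k),
    # radially weighted by rf_k; dc_i/dt = (rf_i F_i - rf_{i+1} F_{i+1}) / (r_i dr)
    g = D / dr * rf  # r-weighted conductance
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    inv = 1.0 / (r_centers * dr)
    # contribution of face k to cell k-1 (outflow) and cell k (inflow)
    diag[:-1] -= g * bm * inv[:-1]
    upper[:-1] += g * bp * inv[:-1]
    lower[1:] += g * bm * inv[1:]
    diag[1:] -= g * bp * inv[1:]
    data = []
    rows = []
    cols = []
    for i in range(n):
        rows.append(i)
        cols.append(i)
        data.append(diag[i])
        if i > 0:
            rows.append(i)
            cols.append(i - 1)
            data.append(lower[i])
        if i < n - 1:
            rows.append(i)
            cols.append(i + 1)
            data.append(upper[i])
    return csc_matrix((data, (rows, cols)), shape=(n, n))


def _analytic_no_diffusion(
    r: np.ndarray, t: float, s_sec: float, omega2: float, meniscus: float, loading: float
) -> np.ndarray:
    """Convection-only solution: a step boundary at r_m exp(s w^2 t) with the
    plateau diluted by exp(-2 s w^2 t) (radial dilution law)."""
    swt = s_sec * omega2 * t
    boundary = meniscus * math.exp(swt)
    plateau = loading * math.exp(-2.0 * swt)
    return np.where(r >= boundary, plateau, 0.0)


def solve_lamm(
    species: list[SpeciesParams],
    geometry: CellGeometry,
    schedule: ScanSchedule,
    loading: list[float],
    channel: str = "signal",
    noise: NoiseModel | None = None,
    ctx: SolventContext | None = None,
    courant: float = 0.5,
    analytic_no_diffusion: bool = False,
    description: str | None = None,
) -> ScanSet:
    """Simulate sedimentation-velocity scans for non-interacting species.

    Parameters
    ----------
    species : the sedimenting species; each contributes
        ``coeff(channel) * c_k(r, t)`` to the recorded signal.
    loading : initial (uniform) molar concentration per species.
    channel : which signal channel to record.
    noise : optional seeded Gaussian noise/baseline applied to the signal.
    courant : advective Courant bound used to pick the time step.
    analytic_no_diffusion : evaluate the closed-form zero-diffusion solution
        instead of the finite-volume solve (required for species with D=0).

    Returns
    -------
    ScanSet with one profile per scheduled scan.
    """
    if len(species) != len(loading):
        raise ValueError("need one loading concentration per species")
    if any(c < 0 for c in loading):
        raise ValueError("loadings must be >= 0")
    ctx = ctx or SolventContext(temperature_K=geometry.temperature_C + 273.15)

    n = schedule.n_radial_points
    dr = (geometry.bottom_cm - geometry.meniscus_cm) / n
    r = geometry.meniscus_cm + dr * (np.arange(n) + 0.5)
    times = schedule.times
    omega2 = geometry.omega2

    total = np.zeros((len(times), n))
    for sp, c0 in zip(species, loading):
        coeff = sp.coeff(channel)
        if coeff == 0.0 or c0 == 0.0:
            continue
        s_sec = sp.s * SVEDBERG
        if analytic_no_diffusion:
            for i, t in enumerate(times):
                total[i] += coeff * _analytic_no_diffusion(
                    r, t, s_sec, omega2, geometry.meniscus_cm, c0
                )
            continue
        D = sp.resolve_D(ctx)
        if D <= 0:
            raise ValueError(
                f"species {sp.name!r} has D <= 0; use analytic_no_diffusion=True "
                "for the convection-only closed form"
            )
        A = _transport_matrix(r, dr, s_sec, D, omega2)
        v_max = s_sec * omega2 * geometry.bottom_cm
        dt_max = courant * dr / v_max
        c = np.full(n, float(c0))
        t_now = 0.0
        lu_cache: dict[float, tuple] = {}
        eye = identity(n, format="csc")
        for i, t in enumerate(times):
            span = t - t_now
            if span > 0:
                nsteps = max(1, math.ceil(span / dt_max))
                dt = span / nsteps
                key = round(dt, 9)
                if key not in lu_cache:
                    lhs = splu((eye - (dt / 2.0) * A).tocsc())
                    rhs = (eye + (dt / 2.0) * A).tocsr()
                    lu_cache[key] = (lhs, rhs)
                lhs, rhs = lu_cache[key]
                for _ in range(nsteps):
                    c = lhs.solve(rhs.dot(c))
                t_now = t
            if not np.all(np.isfinite(c)):
                raise LammInstabilityError(
                    f"non-finite concentrations for species {sp.name!r} at t={t:.0f} s"
                )
            total[i] += coeff * c

    if noise is not None:
        total = noise.apply(total)

    return ScanSet(
        channel=channel,
        radii_cm=r,
        times_s=times,
        signals=total,
        rpm=geometry.rpm,
        temperature_C=geometry.temperature_C,
        description=description or f"simulated SV run, {geometry.rpm:.0f} rpm",
        meniscus_cm=geometry.meniscus_cm,
    )
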
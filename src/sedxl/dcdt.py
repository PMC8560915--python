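"""Time-derivative (dc/dt) analysis of sedimentation-velocity scans.

Adjacent scan pairs inside a user-selected window are differenced to
approximate dc/dt at the pair's mean time t_bar. Each radius maps to an
apparent sedimentation coefficient

    s* = ln(r / r_m) / (omega^2 * t_bar)

and the pair's difference curve is scaled by the conventional
time-derivative transform to an apparent distribution g(s*); pair curves
are interpolated onto a common s* grid and averaged. Peaks are then
characterized by sum-of-Gaussians least squares, and weight-average
sedimentation coefficients can be taken over any s* window.

Flexible scan-range selection matters in practice: early pairs carry the
steepest boundaries (best signal) but compressed s* resolution, late pairs
suffer back-diffusion from the cell bottom; mid-run windows are the usual
choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .constants import SVEDBERG
from .scans import ScanSet

__all__ = [
    "GsDistribution",
    "PeakFit",
    "dcdt_curves",
    "gs_distribution",
    "fit_peaks",
    "weight_average_s",
]

#: radii closer than this to the meniscus are excluded (cm)
MENISCUS_EXCLUSION_CM = 0.02


@dataclass
class GsDistribution:
    """Apparent sedimentation-coefficient distribution g(s*).

    ``normalization`` is one of ``"area"`` (trapezoidal integral 1),
    ``"max"`` (peak height 1) or ``"raw"`` (signal units, linear in
    loading).
    """

    s_grid: np.ndarray  # Svedberg, increasing
    g: np.ndarray
    normalization: str
    n_scan_pairs: int

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if self.s_grid.shape != self.g.shape:
            raise ValueError("s_grid and g must have the same shape")

    @property
    def mode(self) -> float:
        """s* at the maximum of g."""
        return float(self.s_grid[np.argmax(self.g)])


@dataclass
class PeakFit:
    """One Gaussian component of a fitted g(s*) distribution."""

    center_s: float
    sigma_s: float
    amplitude: float
    fit_rmse: float


def dcdt_curves(
    scans: ScanSet,
    scan_range: tuple[int, int] | None = None,
    radial_range: tuple[float, float] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Difference adjacent scan pairs into (s*, dc/dt) curves.

    Parameters
    ----------
    scans : the scan set (shared radial grid, constant rpm).
    scan_range : (first, last) zero-based inclusive scan indices; default all.
    radial_range : (rmin, rmax) in cm; default from meniscus exclusion to the
        back-diffusion clip point.

    Returns one ``(s_star, dcdt)`` pair per adjacent scan pair, ordered by
    time. s* is in Svedberg and increases along each curve.
    """
    lo, hi = scan_range if scan_range is not None else (0, scans.n_scans - 1)
    if hi < 0:
        hi += scans.n_scans
    if hi - lo + 1 < 2:
        raise ValueError("scan window must contain at least 2 scans")
    times = scans.times_s[lo : hi + 1]
    dts = np.diff(times)
    if dts.size > 1 and (dts.max() - dts.min()) > 0.05 * dts.mean():
        warnings.warn("scan intervals vary by more than 5% across the window")

    r_m = scans.meniscus
    radii = scans.radii_cm
    if radial_range is None:
        rmin = r_m + MENISCUS_EXCLUSION_CM
        rmax = _back_diffusion_clip(scans, lo, hi)
    else:
        rmin, rmax = radial_range
        if rmin < radii[0] or rmax > radii[-1]:
            raise ValueError("radial window outside the data")
    mask = (radii > max(rmin, r_m)) & (radii <= rmax)
    if not mask.any():
        raise ValueError("radial window excludes all data points")
    r = radii[mask]
    omega2 = scans.omega**2

    curves = []
    for i in range(lo, hi):
        t_bar = 0.5 * (scans.times_s[i] + scans.times_s[i + 1])
        dt = scans.times_s[i + 1] - scans.times_s[i]
        dcdt = (scans.signals[i + 1, mask] - scans.signals[i, mask]) / dt
        s_star = np.log(r / r_m) / (omega2 * t_bar) / SVEDBERG
        curves.append((s_star, dcdt))
    return curves


def _back_diffusion_clip(scans: ScanSet, lo: int, hi: int) -> float:
    """Clip radius where back-diffusion from the bottom is detected in the
    last scan of the window: walking inward from the bottom, the first
    radius where the signal stops rising toward the bottom."""
    sig = scans.signals[hi]
    radii = scans.radii_cm
    slope = np.gradient(sig, radii)
    scale = max(np.abs(sig).max(), 1e-30)
    # search the outer 20% of the column for a persistent positive slope
    n = len(radii)
    start = int(0.8 * n)
    rising = slope[start:] > 0.5 * scale / (radii[-1] - radii[0])
    idx = None
    for k in range(len(rising) - 1, -1, -1):
        if not rising[k]:
            idx = start + k
            break
    if idx is None:
        idx = start
    return float(radii[idx])


def gs_distribution(
    curves: list[tuple[np.ndarray, np.ndarray]],
    scans: ScanSet,
    scan_range: tuple[int, int] | None = None,
    s_grid: np.ndarray | None = None,
    normalization: str = "area",
) -> GsDistribution:
    """Transform dc/dt pair curves to an averaged g(s*) distribution.

    Each pair's difference curve is scaled pointwise by the time-derivative
    factor omega^2 * t_bar^2 / ln(r/r_m) * (r/r_m)^2 (with the sign chosen
    so depletion of the boundary appears as positive mass), interpolated to
    a common s* grid, averaged across pairs, floored at zero and normalized.
    """
    if not curves:
        raise ValueError("need at least one dc/dt curve")
    if normalization not in ("area", "max", "raw"):
        raise ValueError(f"unknown normalization {normalization!r}")

    lo, hi = scan_range if scan_range is not None else (0, scans.n_scans - 1)
    if hi < 0:
        hi += scans.n_scans
    omega2 = scans.omega**2
    r_m = scans.meniscus

    if s_grid is None:
        smin = min(c[0][0] for c in curves)
        smax = max(c[0][-1] for c in curves)
        s_grid = np.linspace(smin, smax, 400)
    else:
        s_grid = np.asarray(s_grid, dtype=float)
        smin = min(c[0][0] for c in curves)
        smax = max(c[0][-1] for c in curves)
        if s_grid[0] > smin or s_grid[-1] < smax:
            warnings.warn("s_grid does not cover the data's s* support; clipping")

    acc = np.zeros_like(s_grid)
    for (s_star, dcdt), i in zip(curves, range(lo, hi)):
        t_bar = 0.5 * (scans.times_s[i] + scans.times_s[i + 1])
        # r/r_m = exp(s* w^2 t_bar)
        lnr = s_star * SVEDBERG * omega2 * t_bar
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(
                lnr > 0, omega2 * t_bar**2 / np.where(lnr > 0, lnr, 1.0), 0.0
            ) * np.exp(2.0 * lnr)
        g_pair = -dcdt * factor * SVEDBERG  # per-Svedberg density
        acc += np.interp(s_grid, s_star, g_pair, left=0.0, right=0.0)
    g = acc / len(curves)
    g = np.clip(g, 0.0, None)

    if normalization == "area":
        area = np.trapezoid(g, s_grid)
        if area <= 0:
            raise ValueError("distribution has zero area; cannot area-normalize")
        g = g / area
    elif normalization == "max":
        peak = g.max()
        if peak <= 0:
            raise ValueError("distribution is identically zero; cannot max-normalize")
        g = g / peak
    return GsDistribution(
        s_grid=s_grid, g=g, normalization=normalization, n_scan_pairs=len(curves)
    )


def _multi_gauss(params: np.ndarray, s: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(s)
    for j in range(k):
        a, mu, sig = params[3 * j : 3 * j + 3]
        out += a * np.exp(-0.5 * ((s - mu) / sig) ** 2)
    return out


def fit_peaks(
    gs: GsDistribution,
    n_peaks: int | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> list[PeakFit]:
    """Fit a sum of Gaussians to g(s*) and return the components sorted by
    center (ascending; the saturated-complex peak — highest s — is last).

    If ``n_peaks`` is omitted, peaks are seeded from local maxima of at
    least 5% of the global maximum (ties between equal-height maxima broken
    toward lower s). Fitting is multi-start least squares with jittered
    restarts; centers are bounded inside the s* grid.
    """
    s, g = gs.s_grid, gs.g
    gmax = g.max()
    if gmax <= 0:
        raise ValueError("distribution is identically zero; nothing to fit")

    idx, _ = find_peaks(g, height=0.05 * gmax)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(g))])
    order = np.argsort(-g[idx], kind="stable")  # stable: ties toward lower s
    if n_peaks is not None:
        if n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        idx = idx[order[:n_peaks]] if len(idx) >= n_peaks else idx
        while len(idx) < n_peaks:  # pad with the global max if under-seeded
            idx = np.append(idx, int(np.argmax(g)))
    k = len(idx)

    span = s[-1] - s[0]
    p0 = []
    for i in idx:
        p0.extend([g[i], s[i], max(span / 20.0, 1e-3)])
    p0 = np.array(p0)
    lb = np.tile([0.0, s[0], 1e-6], k)
    ub = np.tile([np.inf, s[-1], span], k)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts):
        start = p0 if attempt == 0 else np.clip(
            p0 * (1.0 + 0.2 * rng.standard_normal(p0.shape)), lb + 1e-12, ub - 1e-12
        )
        try:
            res = least_squares(
                lambda p: _multi_gauss(p, s, k) - g, start, bounds=(lb, ub), xtol=1e-14,
                ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and best.cost > 1e-3 * float(np.sum(g**2)):
        residual = math.nan if best is None else math.sqrt(2 * best.cost / len(s))
        raise RuntimeError(f"Gaussian fit failed to converge (residual {residual:.3g})")

    rmse = math.sqrt(2.0 * best.cost / len(s))
    fits = [
        PeakFit(
            center_s=float(best.x[3 * j + 1]),
            sigma_s=float(best.x[3 * j + 2]),
            amplitude=float(best.x[3 * j]),
            fit_rmse=rmse,
        )
        for j in range(k)
    ]
    fits.sort(key=lambda f: f.center_s)
    return fits


def weight_average_s(gs: GsDistribution, s_window: tuple[float, float] | None = None) -> float:
    """Signal-weighted average sedimentation coefficient over an s* window.

    integral(s g ds) / integral(g ds); the window defaults to the full grid.
    """
    if s_window is None:
        mask = np.ones_like(gs.s_grid, dtype=bool)
    else:
        mask = (gs.s_grid >= s_window[0]) & (gs.s_grid <= s_window[1])
    s, g = gs.s_grid[mask], gs.g[mask]
    if len(s) < 2:
        raise ValueError("window contains too few grid points")
    denom = np.trapezoid(g, s)
    if denom <= 0:
        raise ValueError("zero signal mass in the requested window")
    return float(np.trapezoid(s * g, s) / denom)
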
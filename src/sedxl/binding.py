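"""Mass-action speciation, hyperbolic K_D fitting of sedimentation
titrations, and fluorescent degree-of-labeling arithmetic.

The K_D of a 1:1 receptor-ligand equilibrium is estimated from a
sedimentation-velocity titration: at each total ligand concentration c the
highest-s fitted g(s*) peak is taken as the reaction-boundary position, and

    s_peak(c) = s_free + (s_sat - s_free) * c / (K_D + c)

is fitted by nonlinear least squares (the rectangular-hyperbola /
"Michaelis-Menten" form). The abscissa is total ligand concentration; with
the labeled receptor far below K_D this is an excellent approximation to
free ligand and it mirrors how such titrations are conventionally fitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "equilibrate",
    "TitrationPoint",
    "BindingTitrationModel",
    "BindingFitResults",
    "fit_kd",
    "LabelingInput",
    "degree_of_labeling",
]


def equilibrate(a_total: float, b_total: float, kd: float) -> tuple[float, float, float]:
    """Equilibrium speciation of A + B <-> AB with dissociation constant kd.

    Returns ``(free_a, free_b, complex)``. The complex concentration is the
    smaller root of the mass-action quadratic,

        AB = ((a + b + kd) - sqrt((a + b + kd)^2 - 4 a b)) / 2,

    which conserves both totals exactly and is non-negative for all valid
    inputs (the discriminant (a - b)^2 + kd (kd + 2a + 2b) is >= 0).
    """
    if a_total < 0 or b_total < 0:
        raise ValueError("total concentrations must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be positive")
    ssum = a_total + b_total + kd
    disc = ssum * ssum - 4.0 * a_total * b_total
    ab = 0.5 * (ssum - math.sqrt(max(disc, 0.0)))
    ab = min(max(ab, 0.0), a_total, b_total)
    return a_total - ab, b_total - ab, ab


@dataclass(frozen=True)
class TitrationPoint:
    """One titration observation: total ligand concentration (molar) and the
    highest-s fitted peak (Svedberg)."""

    ligand_conc: float
    s_peak: float

    def __post_init__(self) -> None:
        if self.ligand_conc < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class BindingFitResults:
    """Hyperbolic titration fit: estimates, asymptotic standard errors and
    diagnostics."""

    kd: float
    s_free: float
    s_sat: float
    kd_se: float
    s_free_se: float
    s_sat_se: float
    rmse: float
    unreliable: bool
    n_points: int

    @property
    def params(self) -> dict:
        return {"kd": self.kd, "s_free": self.s_free, "s_sat": self.s_sat}

    def summary(self) -> str:
        flag = "  [WARNING: no saturation curvature; kd unreliable]" if self.unreliable else ""
        return "\n".join(
            [
                "Hyperbolic sedimentation titration fit",
                f"  n points : {self.n_points}",
                f"  K_D      : {self.kd * 1e6:.3g} uM  (+/- {self.kd_se * 1e6:.2g}){flag}",
                f"  s_free   : {self.s_free:.3f} S  (+/- {self.s_free_se:.2g})",
                f"  s_sat    : {self.s_sat:.3f} S  (+/- {self.s_sat_se:.2g})",
                f"  rmse     : {self.rmse:.4g} S",
            ]
        )


class BindingTitrationModel:
    """s_peak(c) = s_free + (s_sat - s_free) c / (K_D + c) fitted to a
    sedimentation titration.

    Parameters
    ----------
    conc : total ligand concentrations, molar.
    s_peak : highest-s fitted peak per concentration, Svedberg.
    """

    def __init__(self, conc, s_peak):
        self.conc = np.asarray(conc, dtype=float)
        self.s_peak = np.asarray(s_peak, dtype=float)
        if self.conc.shape != self.s_peak.shape:
            raise ValueError("conc and s_peak must have the same length")
        if len(self.conc) < 4:
            raise ValueError("need at least 4 titration points")
        if len(np.unique(self.conc)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_points(cls, points: list[TitrationPoint]) -> "BindingTitrationModel":
        return cls([p.ligand_conc for p in points], [p.s_peak for p in points])

    @staticmethod
    def _predict(params: np.ndarray, c: np.ndarray) -> np.ndarray:
        kd, s_free, s_sat = params
        return s_free + (s_sat - s_free) * c / (kd + c)

    def fit(self) -> BindingFitResults:
        """Multi-start nonlinear least squares; initial K_D guesses at
        {0.1, 1, 10} x the midpoint concentration, tie broken by rmse."""
        c, y = self.conc, self.s_peak
        cmid = np.median(c[c > 0]) if np.any(c > 0) else 1e-6
        s_lo, s_hi = float(y.min()), float(y.max())
        best = None
        for kd0 in (0.1 * cmid, cmid, 10.0 * cmid):
            p0 = np.array([kd0, s_lo, s_hi if s_hi > s_lo else s_lo + 1e-3])
            try:
                res = least_squares(
                    lambda p: self._predict(p, c) - y,
                    p0,
                    bounds=([1e-15, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("titration fit failed from every start")

        resid = self._predict(best.x, c) - y
        dof = max(len(c) - 3, 1)
        s2 = float(resid @ resid) / dof
        rmse = math.sqrt(float(resid @ resid) / len(c))
        # asymptotic covariance from the Jacobian at the solution
        J = best.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(3, np.inf)

        kd, s_free, s_sat = best.x
        span = abs(s_sat - s_free)
        # no curvature: the data never bend toward saturation, so kd and
        # s_sat trade off freely
        unreliable = (
            span <= 3.0 * rmse + 1e-9
            or kd > 10.0 * c.max()
            or (np.isfinite(se[0]) and se[0] > abs(kd))
        )
        if unreliable:
            warnings.warn("titration shows no saturation curvature; kd is unreliable")
        if s_sat < s_free:
            kd_order = "s_sat < s_free: boundary decreases with ligand"
            warnings.warn(kd_order)
        return BindingFitResults(
            kd=float(kd),
            s_free=float(s_free),
            s_sat=float(s_sat),
            kd_se=float(se[0]),
            s_free_se=float(se[1]),
            s_sat_se=float(se[2]),
            rmse=rmse,
            unreliable=bool(unreliable),
            n_points=len(c),
        )


def fit_kd(points: list[TitrationPoint]) -> BindingFitResults:
    """Fit the hyperbolic binding model to titration points (see
    :class:`BindingTitrationModel`)."""
    return BindingTitrationModel.from_points(points).fit()


@dataclass(frozen=True)
class LabelingInput:
    """UV/Vis readings for fluorophore degree-of-labeling determination.

    CF280 is the dye's 280-nm correction factor and eps_dye its molar
    extinction coefficient at the absorption maximum (defaults are the
    manufacturer's values for maleimide dyes of the ATTO 488 class).
    ``protein_conc`` is the mass concentration in g/L.
    """

    A280: float
    A500: float
    MW: float  # g/mol
    protein_conc: float  # g/L
    CF280: float = 0.09
    eps_dye: float = 90_000.0  # M^-1 cm^-1

    def __post_init__(self) -> None:
        if self.A280 < 0 or self.A500 < 0:
            raise ValueError("absorbances must be >= 0")
        if self.eps_dye <= 0:
            raise ValueError("eps_dye must be positive")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")


def degree_of_labeling(inp: LabelingInput) -> tuple[float, float]:
    """Dye-corrected protein absorbance and mean fluorophores per molecule.

    A_protein = A280 - A500 * CF280;
    DOL = A500 / (c_molar * eps_dye) with c_molar = protein_conc / MW and a
    1-cm path length — equivalently A500 * MW / (protein_conc * eps_dye).
    Warns above DOL 5 (implausible labeling density).
    """
    a_protein = inp.A280 - inp.A500 * inp.CF280
    dol = inp.A500 * inp.MW / (inp.protein_conc * inp.eps_dye)
    if dol > 5:
        warnings.warn(f"DOL = {dol:.2f} fluorophores per molecule is implausibly high")
    return a_protein, dol
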
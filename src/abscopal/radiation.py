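"""Radiation dose-response curves and biologically-effective-dose algebra.

Two curves interpolate the calibrated per-dose response to untested doses:

* the linear-quadratic survival fraction with a Lea-Catcheside-type
  protraction factor,  SF(D) = exp(-alpha*D - beta*G(lam*T)*D^2)  with
  G(x) = 2*(x + exp(-x) - 1)/x^2 and T = D / dose_rate the delivery time,
  which corrects the quadratic term for sublethal-damage repair (rate
  ``lam``) during a finite delivery; and
* a capped log-normal shape for the fraction of killed cells dying
  immunogenically,  AI(D) = min((gamma/D)*exp(-(ln D - mu)^2/rho), 1),
  which captures the non-monotonic dose dependence of immunogenic death.

The survival values these curves are fitted to are *in vivo volumetric*
survival fractions, so alpha/beta here are not directly comparable to
clonogenic LQ parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .parameters import DoseResponseTable

__all__ = [
    "LQParameters",
    "ImmunogenicDeathParameters",
    "DoseResponseModel",
    "survival_fraction",
    "immunogenic_fraction",
    "protraction_factor",
    "fit_lq",
    "fit_immunogenic",
    "bed",
    "dose_per_fraction_for_bed",
    "default_dose_response_model",
]


@dataclass
class LQParameters:
    """Linear-quadratic survival parameters with protraction.

    ``alpha`` (1/Gy) and ``beta`` (1/Gy^2) are the LQ coefficients, ``lam``
    the sublethal-damage repair rate (1/min), and ``dose_rate`` the delivery
    rate in Gy/min (default 6.0, i.e. 600 cGy/min as delivered in the
    calibrating experiment).
    """

    alpha: float
    beta: float
    lam: float
    dose_rate: float = 6.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.dose_rate <= 0:
            raise ValueError("dose_rate must be > 0")


@dataclass
class ImmunogenicDeathParameters:
    """Capped log-normal immunogenic-death parameters.

    ``gamma`` (Gy) scales the curve, ``mu`` centers it in log-dose and
    ``rho`` is the squared log-width.
    """

    gamma: float
    mu: float
    rho: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")


def protraction_factor(x: float) -> float:
    """Dose-protraction factor G(x) = 2*(x + exp(-x) - 1) / x^2.

    Monotonically decreasing from 1 (instantaneous delivery, x -> 0) toward
    0; evaluated by its limit for x < 1e-6 to avoid cancellation.
    """
    if x < 0:
        raise ValueError("protraction argument must be >= 0")
    if x < 1e-6:
        return 1.0 - x / 3.0
    # expm1 avoids the x + exp(-x) - 1 cancellation for small x
    return 2.0 * (x + math.expm1(-x)) / (x * x)


def survival_fraction(D: float, lq: LQParameters) -> float:
    """Surviving fraction of viable tumor volume after one fraction of D Gy."""
    if D < 0:
        raise ValueError("dose must be >= 0")
    if D == 0:
        return 1.0
    T = D / lq.dose_rate
    G = protraction_factor(lq.lam * T)
    return math.exp(-lq.alpha * D - lq.beta * G * D * D)


def immunogenic_fraction(D: float, p: ImmunogenicDeathParameters) -> float:
    """Fraction of radiation-killed cells undergoing immunogenic death."""
    if D <= 0:
        raise ValueError("dose must be > 0")
    return min((p.gamma / D) * math.exp(-((math.log(D) - p.mu) ** 2) / p.rho), 1.0)


@dataclass
class DoseResponseModel:
    """Continuous SF/AI dose-response, optionally pinned to a calibrated table.

    At doses present in ``table`` the tabulated values are returned verbatim
    (the curves exist to interpolate *untested* doses); elsewhere the fitted
    curves are evaluated.
    """

    lq: LQParameters
    immunogenic: ImmunogenicDeathParameters
    table: DoseResponseTable | None = None

    def sf(self, D: float) -> float:
        if self.table is not None and D in self.table:
            return self.table.lookup(D)[0]
        return survival_fraction(D, self.lq)

    def ai(self, D: float) -> float:
        if self.table is not None and D in self.table:
            return self.table.lookup(D)[1]
        return immunogenic_fraction(D, self.immunogenic)

    def sf_ai(self, D: float) -> tuple[float, float]:
        return self.sf(D), self.ai(D)


def default_dose_response_model(table: DoseResponseTable | None = None) -> DoseResponseModel:
    """Dose-response model with the published curve parameters.

    alpha = 2.8e-8 /Gy, beta = 0.0132 /Gy^2, lam = 2.0358 /min at 6 Gy/min;
    gamma = 14.173 Gy, mu = 2.448, rho = 0.232.  If ``table`` is omitted the
    calibrated three-dose table is attached.
    """
    if table is None:
        from .parameters import default_parameters
        table = default_parameters()[1]
    return DoseResponseModel(
        lq=LQParameters(alpha=2.8e-8, beta=0.0132, lam=2.0358, dose_rate=6.0),
        immunogenic=ImmunogenicDeathParameters(gamma=14.173, mu=2.448, rho=0.232),
        table=table,
    )


# ---------------------------------------------------------------------------
# Curve fitting

def _multistart_lsq(residual, bounds_lo, bounds_hi, starts, seed):
    rng = np.random.default_rng(seed)
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    best = None
    for _ in range(starts):
        x0 = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("dose-response fit failed to converge from any start")
    return best


def fit_lq(table: DoseResponseTable, dose_rate: float = 6.0,
           n_starts: int = 20, seed: int = 0) -> LQParameters:
    """Fit (alpha, beta, lam) of the protracted LQ curve to tabulated SF values.

    Requires at least three dose/SF points.  Multistart bounded least squares
    (log-uniform starts, fixed seed) keeps the shipped result deterministic on
    the non-convex 3-point surface.
    """
    doses = np.array(table.doses, dtype=float)
    if doses.size < 3:
        raise ValueError("fit_lq needs at least 3 dose/SF points")
    sf_obs = np.array([table.entries[d][0] for d in table.doses])

    def residual(x):
        lq = LQParameters(alpha=x[0], beta=x[1], lam=x[2], dose_rate=dose_rate)
        return np.array([survival_fraction(d, lq) for d in doses]) - sf_obs

    best = _multistart_lsq(residual, [1e-10, 1e-6, 1e-3], [2.0, 1.0, 60.0],
                           n_starts, seed)
    return LQParameters(alpha=best.x[0], beta=best.x[1], lam=best.x[2],
                        dose_rate=dose_rate)


def fit_immunogenic(table: DoseResponseTable, n_starts: int = 20,
                    seed: int = 0) -> ImmunogenicDeathParameters:
    """Fit (gamma, mu, rho) of the capped log-normal to tabulated AI values.

    A degenerate (near-flat) table still returns a valid parameter set but
    triggers a warning, since a flat curve is only approximated.
    """
    doses = np.array(table.doses, dtype=float)
    if doses.size < 3:
        raise ValueError("fit_immunogenic needs at least 3 dose/AI points")
    ai_obs = np.array([table.entries[d][1] for d in table.doses])

    def residual(x):
        p = ImmunogenicDeathParameters(gamma=x[0], mu=x[1], rho=x[2])
        return np.array([immunogenic_fraction(d, p) for d in doses]) - ai_obs

    best = _multistart_lsq(residual, [1e-3, 1e-3, 1e-3], [1e3, 5.0, 20.0],
                           n_starts, seed)
    fitted = ImmunogenicDeathParameters(gamma=best.x[0], mu=best.x[1], rho=best.x[2])
    if np.ptp(ai_obs) < 1e-3:
        warnings.warn("AI table is (near-)constant; log-normal fit is a flat-curve "
                      "approximation", stacklevel=2)
    return fitted


# ---------------------------------------------------------------------------
# BED algebra

def bed(n: int, D: float, theta: float = 20.0) -> float:
    """Biologically effective dose n*D*(1 + D/theta) for n fractions of D Gy."""
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if D <= 0:
        raise ValueError("D must be > 0")
    return n * D * (1.0 + D / theta)


def dose_per_fraction_for_bed(n: int, bed_gy: float, theta: float = 20.0) -> float:
    """Dose per fraction giving total BED ``bed_gy`` in ``n`` daily fractions.

    Positive root of n*D*(1 + D/theta) = bed_gy:
    D = (theta/2) * (-1 + sqrt(1 + 4*bed_gy/(n*theta))).
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if bed_gy <= 0:
        raise ValueError("bed_gy must be > 0")
    return 0.5 * theta * (-1.0 + math.sqrt(1.0 + 4.0 * bed_gy / (n * theta)))
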
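"""Bacterial growth laws from the optimized PTR cell.

Three empirical regularities are reproduced and their phenomenological
constants derived from the model parameters:

* Monod curve: mu = mu_inf [F] / (C1 + [F]) as a function of the external
  food concentration [F].
* Nutritional line: Phi_R = Phi_R_min + mu / kappa_t when growth rate is
  varied through medium quality, with
  Phi_R_min = d_T / (rho + d_T - d_R) and kappa_t = rho + d_T - d_R.
* Translational line: Phi_R = Phi_R_max - mu / kappa_n when growth rate is
  varied through ribosome efficiency, with
  Phi_R_max = (nu - d_T) / (nu - d_T + d_R) and kappa_n = nu - d_T + d_R.

The two experimental protocols are implemented as parameter sweeps over the
medium quality q (K_P = q k_P) and over the catalytic efficiency k, each row
holding the optimized steady state, followed by an ordinary least-squares
line fit of Phi_R against mu_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import PTRParameters
from . import optimize as opt
from . import steady_state as sstate


class UnsupportedCaseError(ValueError):
    """A closed form is requested outside the regime it was derived for."""


@dataclass(frozen=True)
class MediumModel:
    """Map from external food concentration [F] to nutritional efficiency nu.

    ``linear`` form: nu = k1 [F] (uptake far from transporter saturation);
    ``michaelis_menten`` form: nu = nu0 [F]/(K + [F]) (transport limited).
    ``q`` and ``k_P`` support the K_P = q * k_P parametrization of medium
    quality used by the sweeps.
    """

    form: str = "linear"
    k1: Optional[float] = None
    nu0: Optional[float] = None
    K: Optional[float] = None
    F: Optional[float] = None
    q: float = 1.0
    k_P: Optional[float] = None

    def __post_init__(self):
        if self.form == "linear":
            if self.k1 is None or self.k1 < 0:
                raise ValueError("linear form requires k1 >= 0")
        elif self.form == "michaelis_menten":
            if self.nu0 is None or self.K is None or self.nu0 < 0 or self.K <= 0:
                raise ValueError("michaelis_menten form requires nu0 >= 0, K > 0")
        else:
            raise ValueError(f"unknown medium form {self.form!r}")


@dataclass(frozen=True)
class PhenomenologicalConstants:
    """The six growth-law constants (Monod pair optional)."""

    Phi_R_min: float
    kappa_t: float
    Phi_R_max: float
    kappa_n: float
    mu_inf: Optional[float] = None
    C1: Optional[float] = None
    valid: bool = True
    notes: tuple = ()


@dataclass(frozen=True)
class GrowthLawFit:
    """OLS line fit of Phi_R against mu_max for one sweep protocol."""

    branch: str  # "nutritional" (positive slope) | "translational" (negative)
    slope: float
    intercept: float
    r_squared: float
    Phi_R_min: Optional[float] = None
    kappa_t: Optional[float] = None
    Phi_R_max: Optional[float] = None
    kappa_n: Optional[float] = None


def nu_from_medium(medium: MediumModel, F: Optional[float] = None) -> float:
    """Nutritional efficiency nu([F]); nondecreasing in [F] with nu(0) = 0."""
    conc = medium.F if F is None else F
    if conc is None:
        raise ValueError("food concentration F not supplied")
    if conc < 0:
        raise ValueError("F must be nonnegative")
    if medium.form == "linear":
        return medium.k1 * conc
    return medium.nu0 * conc / (medium.K + conc)


def monod_constants(medium: MediumModel, rho: float, *,
                    d_T: float = 0.0, d_R: float = 0.0) -> tuple:
    """Monod constants (mu_inf, C1) of the optimized growth rate.

    Closed forms exist for the zero-degradation case, where
    mu_max = rho nu / (rho + nu):

    * linear nu = k1 [F]:  mu_inf = rho,  C1 = rho / k1;
    * Michaelis-Menten nu = nu0 [F]/(K + [F]):
      mu_inf = rho nu0 / (rho + nu0),  C1 = K / (1 + nu0/rho).

    With nonzero degradation no closed Monod form is derived; build the
    curve numerically with :func:`sweep_medium_quality` instead.
    """
    if d_T != 0.0 or d_R != 0.0:
        raise UnsupportedCaseError(
            "Monod constants are derived for d_T = d_R = 0 only")
    if rho <= 0:
        raise ValueError("rho must be positive")
    if medium.form == "linear":
        if medium.k1 == 0:
            raise ValueError("k1 must be positive for Monod constants")
        return rho, rho / medium.k1
    return (rho * medium.nu0 / (rho + medium.nu0),
            medium.K / (1.0 + medium.nu0 / rho))


def phenomenological_constants(params: PTRParameters,
                               medium: Optional[MediumModel] = None
                               ) -> PhenomenologicalConstants:
    """Growth-law constants of the two linear Phi_R(mu) relations.

    Requires kappa_t = rho + d_T - d_R > 0 and kappa_n = nu - d_T + d_R > 0;
    violations are flagged (``valid=False``) rather than raised.  If a
    zero-degradation ``medium`` is supplied the Monod pair is included.
    """
    nu, rho = params.nu, params.rho
    kappa_t = rho + params.d_T - params.d_R
    kappa_n = nu - params.d_T + params.d_R
    notes = []
    valid = True
    if kappa_t <= 0:
        valid = False
        notes.append("kappa_t <= 0: nutritional line undefined")
    if kappa_n <= 0:
        valid = False
        notes.append("kappa_n <= 0: translational line undefined")
    Phi_R_min = params.d_T / kappa_t if kappa_t > 0 else math.nan
    Phi_R_max = (nu - params.d_T) / kappa_n if kappa_n > 0 else math.nan
    mu_inf = C1 = None
    if medium is not None and params.d_T == 0.0 and params.d_R == 0.0:
        mu_inf, C1 = monod_constants(medium, rho)
    return PhenomenologicalConstants(Phi_R_min=Phi_R_min, kappa_t=kappa_t,
                                     Phi_R_max=Phi_R_max, kappa_n=kappa_n,
                                     mu_inf=mu_inf, C1=C1, valid=valid,
                                     notes=tuple(notes))


def _optimized_row(params: PTRParameters) -> dict:
    """Numeric and large-m optimum observables for one parameter set."""
    row = {"nu": params.nu, "rho": params.rho}
    try:
        num = opt.optimize_fr_numeric(params)
        row.update(f_max=num.f_max, mu_max=num.mu_max, Phi_R=num.Phi_R_opt,
                   T_over_R=num.T_over_R_opt, feasible=True)
    except opt.NoOptimumError:
        row.update(f_max=math.nan, mu_max=math.nan, Phi_R=math.nan,
                   T_over_R=math.nan, feasible=False)
    lm = opt.large_m_optimum(params)
    row.update(f_max_large_m=lm.f_max, mu_max_large_m=lm.mu_max,
               Phi_R_large_m=lm.Phi_R_opt)
    return row


def sweep_medium_quality(base_params: PTRParameters,
                         q_values: Optional[Sequence[float]] = None,
                         k_P: Optional[float] = None) -> pd.DataFrame:
    """Optimized steady states while the medium quality q is varied.

    ``K_P = q * k_P`` with ``k_P`` defaulting to the base parameters' K_P
    (i.e. the base set is taken as the q = 1 medium).  Default grid: 12
    log-spaced qualities in [0.5, 64].  Rows with no optimum are flagged,
    not dropped.
    """
    if q_values is None:
        q_values = np.geomspace(0.5, 64.0, 12)
    q_values = np.asarray(q_values, dtype=float)
    if np.any(q_values <= 0):
        raise ValueError("q values must be positive")
    kp = base_params.K_P if k_P is None else k_P
    rows = []
    for q in q_values:
        row = {"q": q}
        row.update(_optimized_row(base_params.replace(K_P=q * kp)))
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_ribosomal_efficiency(base_params: PTRParameters,
                               k_values: Optional[Sequence[float]] = None
                               ) -> pd.DataFrame:
    """Optimized steady states while the catalytic efficiency k is varied.

    Default grid: 8 values obtained by successive halving from the base k.
    """
    if k_values is None:
        k_values = base_params.k * 0.5 ** np.arange(8)
    k_values = np.asarray(k_values, dtype=float)
    if np.any(k_values <= 0):
        raise ValueError("k values must be positive")
    rows = []
    for k in k_values:
        row = {"k": k}
        row.update(_optimized_row(base_params.replace(k=k)))
        rows.append(row)
    return pd.DataFrame(rows)


def fit_growth_law(mu: Sequence[float], Phi_R: Sequence[float],
                   branch: str) -> GrowthLawFit:
    """OLS line through (mu, Phi_R) points, mapped to growth-law constants.

    ``branch="nutritional"``: slope = 1/kappa_t, intercept = Phi_R_min.
    ``branch="translational"``: slope = -1/kappa_n, intercept = Phi_R_max.
    """
    mu = np.asarray(mu, dtype=float)
    Phi_R = np.asarray(Phi_R, dtype=float)
    keep = np.isfinite(mu) & np.isfinite(Phi_R)
    mu, Phi_R = mu[keep], Phi_R[keep]
    if mu.size < 2:
        raise ValueError("need at least two finite points to fit a line")
    slope, intercept = np.polyfit(mu, Phi_R, 1)
    pred = slope * mu + intercept
    ss_res = float(np.sum((Phi_R - pred) ** 2))
    ss_tot = float(np.sum((Phi_R - Phi_R.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if branch == "nutritional":
        return GrowthLawFit(branch, slope, intercept, r2,
                            Phi_R_min=float(intercept),
                            kappa_t=float(1.0 / slope))
    if branch == "translational":
        return GrowthLawFit(branch, slope, intercept, r2,
                            Phi_R_max=float(intercept),
                            kappa_n=float(-1.0 / slope))
    raise ValueError(f"unknown branch {branch!r}")


def monod_curve(base_params: PTRParameters, medium: MediumModel,
                F_values: Sequence[float]) -> pd.DataFrame:
    """Optimized large-m growth rate as a function of food concentration.

    nu([F]) is taken from ``medium`` and K_P = nu * m_T is substituted into
    the base parameters before evaluating mu_max.
    """
    rows = []
    for F in np.asarray(F_values, dtype=float):
        nu = nu_from_medium(medium, F)
        p = base_params.replace(K_P=nu * base_params.m_T)
        rows.append({"F": F, "nu": nu, "mu_max": opt.mumax_large_m(p)})
    return pd.DataFrame(rows)
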
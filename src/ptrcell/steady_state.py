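"""Analytic steady state of the PTR cell.

Substituting the exponential ansatz P, T, R ~ e^(mu t) into the population
equations gives closed-form ratios in terms of mu,

    P/V = (mu + d_R) / K_R
    T/R = (m_R/m_T) (f_T/f_R) (mu + d_R)/(mu + d_T)
    P/R = (m_R/f_R) ((mu + d_R)/mu) [ K_P f_T / (m_T (mu + d_T)) - 1 ]

and a quadratic characteristic equation for the growth rate itself,

    alpha mu^2 - beta mu + gamma = 0,
    alpha = 1 - eps1,  beta = a + b + eps2,  gamma = a b,
    a = nu f_T - d_T,  b = rho f_R - d_R,

where nu = K_P/m_T and rho = k/(m_R v_P) are the nutritional and ribosomal
efficiencies and eps1, eps2 are O(1/m) volume corrections.  The smaller root
mu_- is the physically realised growth rate: simulated trajectories converge
to it, it vanishes in the f_R -> 0 and f_R -> 1 limits (zero degradation),
and the larger root implies negative populations at large m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from typing import Optional

from .parameters import PTRParameters

#: alpha below this threshold triggers the degenerate linear solve.
ALPHA_DEGENERATE = 1e-12


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients of the growth-rate quadratic and their building blocks."""

    alpha: float
    beta: float
    gamma: float
    a: float
    b: float
    eps1: float
    eps2: float
    nu: float
    rho: float
    #: True when eps1 < 1 so the quadratic has a positive leading term.
    well_posed: bool


@dataclass(frozen=True)
class GrowthRateRoots:
    mu_minus: float
    mu_plus: float
    discriminant: float
    feasible: bool
    degenerate: bool  # alpha ~ 0, linear fallback used


@dataclass(frozen=True)
class SteadyState:
    """Balanced-growth observables at a given growth rate."""

    mu: float
    P_over_V: float
    T_over_R: float
    P_over_R: float
    Phi_R: float
    feasible: bool
    reason: Optional[str] = None


def quadratic_coefficients(params: PTRParameters) -> QuadraticCoefficients:
    """All coefficients of the characteristic quadratic for ``params``."""
    nu, rho = params.nu, params.rho
    f_T, f_R = params.f_T, params.f_R
    a = nu * f_T - params.d_T
    b = rho * f_R - params.d_R
    wT = (f_T / params.m_T) * (params.v_T / params.v_P)
    wR = (f_R / params.m_R) * (params.v_R / params.v_P)
    eps1 = wT + wR
    eps2 = wT * params.d_R + wR * params.d_T
    return QuadraticCoefficients(alpha=1.0 - eps1, beta=a + b + eps2,
                                 gamma=a * b, a=a, b=b, eps1=eps1, eps2=eps2,
                                 nu=nu, rho=rho, well_posed=eps1 < 1.0)


def solve_growth_rate(params: PTRParameters) -> GrowthRateRoots:
    """Both roots of the growth-rate quadratic, with mu_- designated physical.

    The quadratic is solved in the cancellation-free form: the larger-
    magnitude root is computed from the formula and the other from the
    product gamma/alpha.  Complex roots are reported as an infeasible state
    (NaN roots), not an exception, so parameter sweeps can traverse them.
    """
    c = quadratic_coefficients(params)
    alpha, beta, gamma = c.alpha, c.beta, c.gamma
    if abs(alpha) < ALPHA_DEGENERATE:
        # eps1 -> 1 is unphysical but must not crash: beta*mu = gamma.
        if beta == 0.0:
            return GrowthRateRoots(math.nan, math.nan, 0.0, False, True)
        return GrowthRateRoots(gamma / beta, math.inf, beta * beta, True, True)
    disc = beta * beta - 4.0 * alpha * gamma
    if disc < 0.0:
        return GrowthRateRoots(math.nan, math.nan, disc, False, False)
    s = math.sqrt(disc)
    if beta >= 0.0:
        mu_plus = (beta + s) / (2.0 * alpha)
        mu_minus = gamma / (alpha * mu_plus) if mu_plus != 0.0 else 0.0
    else:
        mu_minus = (beta - s) / (2.0 * alpha)
        mu_plus = gamma / (alpha * mu_minus) if mu_minus != 0.0 else 0.0

    def polish(mu: float) -> float:
        # near a root collision (small discriminant) the closed form loses
        # half the significant digits; two Newton steps restore them
        for _ in range(2):
            deriv = 2.0 * alpha * mu - beta
            if deriv == 0.0:
                break
            mu -= (alpha * mu * mu - beta * mu + gamma) / deriv
        return mu

    return GrowthRateRoots(polish(mu_minus), polish(mu_plus), disc,
                           True, False)


def ribosomal_fraction(params: PTRParameters, mu: float) -> float:
    """Ribosomal protein fraction Phi_R = m_R R / (m_T T + m_R R).

    Evaluated in two algebraically equivalent forms,

        Phi_R = 1 / (1 + (f_T/f_R)(mu + d_R)/(mu + d_T))
              = f_R + f_T f_R (d_T - d_R) / (mu + f_T d_R + f_R d_T),

    whose agreement is asserted as an internal consistency check.  With
    equal degradation rates Phi_R = f_R for every mu.  ``f_R = 0`` returns
    0 by continuity.
    """
    if params.f_R == 0.0:
        return 0.0
    if mu + params.d_T <= 0 or mu + params.d_R <= 0:
        raise ValueError("require mu + d_T > 0 and mu + d_R > 0")
    ratio = (params.f_T / params.f_R) * (mu + params.d_R) / (mu + params.d_T)
    form1 = 1.0 / (1.0 + ratio)
    denom = mu + params.f_T * params.d_R + params.f_R * params.d_T
    form2 = params.f_R + params.f_T * params.f_R * (params.d_T - params.d_R) / denom
    if abs(form1 - form2) > 1e-12 * max(1.0, abs(form1)):
        raise AssertionError(f"Phi_R forms disagree: {form1} vs {form2}")
    return form1


def _polish_if_root(params: PTRParameters, mu_ld):
    """Refine ``mu`` in extended precision iff it already solves the
    characteristic quadratic to double rounding; other values pass through
    untouched (ratios at arbitrary mu are legitimate queries)."""
    ld = np.longdouble
    f_T, f_R = ld(params.f_T), ld(params.f_R)
    a = ld(params.K_P) / ld(params.m_T) * f_T - ld(params.d_T)
    b = ld(params.k) / (ld(params.m_R) * ld(params.v_P)) * f_R - ld(params.d_R)
    wT = (f_T / ld(params.m_T)) * (ld(params.v_T) / ld(params.v_P))
    wR = (f_R / ld(params.m_R)) * (ld(params.v_R) / ld(params.v_P))
    alpha = ld(1.0) - (wT + wR)
    beta = a + b + wT * ld(params.d_R) + wR * ld(params.d_T)
    gamma = a * b
    q_scale = max(abs(alpha * mu_ld * mu_ld), abs(beta * mu_ld), abs(gamma))
    if q_scale == 0:
        return mu_ld
    for _ in range(3):
        q = alpha * mu_ld * mu_ld - beta * mu_ld + gamma
        if abs(q) > 1e-9 * q_scale:  # not meant as a root: leave it alone
            return mu_ld
        deriv = 2 * alpha * mu_ld - beta
        if deriv == 0:
            break
        mu_ld = mu_ld - q / deriv
    return mu_ld


def steady_ratios(params: PTRParameters, mu: float) -> SteadyState:
    """Balanced-growth ratios and ribosomal fraction at growth rate ``mu``.

    Infeasibility (negative P/R, mu = 0 with d_R = 0, zero K_R) is reported
    through the ``feasible`` flag with a reason, never raised, so sweeps can
    cross infeasible regions.
    """
    nan = math.nan
    if not math.isfinite(mu):
        return SteadyState(mu, nan, nan, nan, nan, False, "mu not finite")
    if mu == 0.0 and params.d_R == 0.0 and params.K_R > 0.0:
        # P/R divides by mu: report the degenerate state, don't guess a limit
        T_over_R = 0.0 if params.d_T > 0 else nan
        return SteadyState(mu, 0.0, T_over_R, nan, nan, False,
                           "P/R undefined at mu = 0 with d_R = 0")
    if mu + params.d_T <= 0 or mu + params.d_R <= 0:
        return SteadyState(mu, nan, nan, nan, nan, False,
                           "mu + d_T and mu + d_R must be positive")
    if params.K_R == 0.0:
        return SteadyState(mu, nan, nan, nan, nan, False,
                           "K_R = 0: ribosomes not produced")
    P_over_V = (mu + params.d_R) / params.K_R
    T_over_R = (params.m_R / params.m_T) * (params.f_T / params.f_R) \
        * (mu + params.d_R) / (mu + params.d_T)
    # The bracket in P/R cancels catastrophically when the precursor pool
    # is nearly empty, amplifying even the final rounding of mu.  Evaluate
    # it in extended precision, and when mu is (to double rounding) a root
    # of the characteristic quadratic, first re-polish it at that precision
    # so the hand-off through a 53-bit float costs nothing.
    ld = np.longdouble
    mu_ld = _polish_if_root(params, ld(mu))
    scale_ld = ld(params.K_P) * ld(params.f_T) \
        / (ld(params.m_T) * (mu_ld + ld(params.d_T)))
    scale = float(scale_ld)
    bracket = float(scale_ld - ld(1.0))
    P_over_R = (params.m_R / params.f_R) * ((mu + params.d_R) / mu) * bracket
    Phi_R = ribosomal_fraction(params, mu)
    # bracket = 0 is marginal feasibility (P/R = 0); allow rounding noise
    feasible = bracket >= -1e-9 * (1.0 + abs(scale))
    return SteadyState(mu, P_over_V, T_over_R, P_over_R, Phi_R, feasible,
                       None if feasible else "negative P/R")


def balanced_state(params: PTRParameters) -> SteadyState:
    """Convenience: physical root mu_- and its steady-state observables."""
    roots = solve_growth_rate(params)
    if not roots.feasible:
        return SteadyState(math.nan, math.nan, math.nan, math.nan, math.nan,
                           False, "complex growth-rate roots")
    return steady_ratios(params, roots.mu_minus)


def ansatz_residuals(params: PTRParameters, ss: SteadyState) -> tuple:
    """Relative residuals of the three balanced-growth equations.

    Populations are reconstructed from the ratios with R = 1 and substituted
    back into mu*P = K_P T - k R P/V, (mu+d_T) T = K_T R P/V and
    (mu+d_R) R = K_R R P/V.  Each residual is normalised by the largest
    flux appearing in its equation (for a nearly empty precursor pool the
    production and consumption terms cancel almost exactly, so the
    difference itself is not a meaningful scale); for an exact steady state
    all three vanish to rounding.
    """
    R = 1.0
    T = ss.T_over_R * R
    P = ss.P_over_R * R
    V = params.v_P * P + params.v_T * T + params.v_R * R
    synth = R * P / V
    lhs = (ss.mu * P, (ss.mu + params.d_T) * T, (ss.mu + params.d_R) * R)
    rhs_ = (params.K_P * T - params.k * synth,
            params.K_T * synth, params.K_R * synth)
    scales = (max(abs(ss.mu * P), params.K_P * T, params.k * synth),
              max(abs(lhs[1]), rhs_[1]),
              max(abs(lhs[2]), rhs_[2]))
    return tuple(abs(l - r) / max(s, 1e-300)
                 for l, r, s in zip(lhs, rhs_, scales))


def report(params: PTRParameters) -> dict:
    """JSON-ready steady-state summary for one parameter set."""
    c = quadratic_coefficients(params)
    roots = solve_growth_rate(params)
    out = {"mu_minus": roots.mu_minus, "mu_plus": roots.mu_plus,
           "discriminant": roots.discriminant, "nu": c.nu, "rho": c.rho,
           "a": c.a, "b": c.b, "feasible": roots.feasible}
    if roots.feasible:
        ss = steady_ratios(params, roots.mu_minus)
        out.update({"ratios": {"P_over_V": ss.P_over_V,
                               "T_over_R": ss.T_over_R,
                               "P_over_R": ss.P_over_R},
                    "Phi_R": ss.Phi_R, "feasible": ss.feasible,
                    "reason": ss.reason})
    return out
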
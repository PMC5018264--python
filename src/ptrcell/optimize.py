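"""Growth-rate maximization over the ribosome allocation f_R.

The regulation assumption: intracellular regulatory mechanisms tune the
fraction of ribosomes making ribosomal protein, f_R, to the value f_max
that maximizes the balanced growth rate mu_-(f_R) at fixed medium and
cellular parameters.  When the residue counts m_T, m_R are large the
optimum has simple closed forms in the two efficiencies nu and rho:

    f_max   = (nu + d_R - d_T) / (nu + rho)
    mu_max  = (rho (nu - d_T) - nu d_R) / (nu + rho)
    Phi_R   = nu / (nu + rho)
    T/R     = (m_R/m_T) (rho/nu)

At the optimum the two sector outputs balance -- (m_T T) nu = (m_R R) rho,
the principle of cellular economy -- and this identity fails off-optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .parameters import PTRParameters
from . import steady_state as sstate


class NoOptimumError(RuntimeError):
    """mu_-(f_R) is infeasible on all of (0, 1)."""


@dataclass(frozen=True)
class OptimumResult:
    f_max: float
    mu_max: float
    Phi_R_opt: float
    T_over_R_opt: float
    method: str  # "numeric" | "large_m"
    economy_residual: float
    flags: tuple = ()


def mu_of_fr(params: PTRParameters, f_R: float) -> float:
    """mu_-(f_R) for optimization: -inf where no feasible steady state."""
    p = params.replace(f_R=float(f_R))
    roots = sstate.solve_growth_rate(p)
    if not roots.feasible or not math.isfinite(roots.mu_minus):
        return -math.inf
    ss = sstate.steady_ratios(p, roots.mu_minus)
    if not ss.feasible:
        return -math.inf
    return roots.mu_minus


def scan_fr(params: PTRParameters, n_grid: int = 256) -> pd.DataFrame:
    """Grid scan of mu_-(f_R) on the open interval (0, 1)."""
    f_values = np.linspace(0.0, 1.0, n_grid + 2)[1:-1]
    mu = np.array([mu_of_fr(params, f) for f in f_values])
    return pd.DataFrame({"f_R": f_values, "mu_minus": mu,
                         "feasible": np.isfinite(mu)})


def economy_residual(params: PTRParameters, T_over_R: float) -> float:
    """Relative gap of the cellular-economy identity (m_T T) nu = (m_R R) rho.

    Outputs are measured per ribosome; the gap is normalised by the larger
    sector output.  Zero at the exact large-m optimum, O(1/m) at the numeric
    optimum, and order unity far from it.
    """
    out_T = params.m_T * T_over_R * params.nu
    out_R = params.m_R * params.rho
    big = max(out_T, out_R)
    if big <= 0:
        raise ValueError("sector outputs must be positive")
    return abs(out_T - out_R) / big


def _observables(params: PTRParameters, f_R: float, mu: float):
    p = params.replace(f_R=f_R)
    ss = sstate.steady_ratios(p, mu)
    return ss.Phi_R, ss.T_over_R, economy_residual(p, ss.T_over_R)


def optimize_fr_numeric(params: PTRParameters, *, n_grid: int = 256,
                        xatol: float = 1e-10) -> OptimumResult:
    """Locate the global maximum of mu_-(f_R) on (0, 1).

    A coarse grid scan (default 256 interior points) guards against boundary
    layers and possible multimodality; bounded scalar maximization then
    refines within the bracketing grid cells.  Ties on a plateau resolve to
    the smallest f_R (first grid argmax).
    """
    scan = scan_fr(params, n_grid=n_grid)
    mu = scan["mu_minus"].to_numpy()
    if not np.isfinite(mu).any():
        raise NoOptimumError("mu_-(f_R) infeasible on all of (0, 1)")
    f_values = scan["f_R"].to_numpy()
    i = int(np.argmax(mu))
    lo = f_values[i - 1] if i > 0 else 0.0
    hi = f_values[i + 1] if i < len(f_values) - 1 else 1.0
    # finite penalty for infeasible points: -inf would poison the
    # parabolic-interpolation steps of the bounded minimizer
    def neg_mu(f):
        mu_f = mu_of_fr(params, f)
        return -mu_f if math.isfinite(mu_f) else 1e6

    res = minimize_scalar(neg_mu, bounds=(lo, hi),
                          method="bounded", options={"xatol": xatol})
    f_max, mu_max = float(res.x), float(-res.fun)
    # the refined point can only improve on the grid point
    if mu[i] > mu_max:
        f_max, mu_max = float(f_values[i]), float(mu[i])
    Phi_R, T_over_R, econ = _observables(params, f_max, mu_max)
    return OptimumResult(f_max=f_max, mu_max=mu_max, Phi_R_opt=Phi_R,
                         T_over_R_opt=T_over_R, method="numeric",
                         economy_residual=econ)


# -- large-m closed forms ---------------------------------------------------

def fmax_large_m(params: PTRParameters) -> float:
    """Optimal allocation (nu + d_R - d_T)/(nu + rho) in the large-m limit."""
    nu, rho = params.nu, params.rho
    if nu + rho <= 0:
        raise ValueError("nu + rho must be positive")
    return (nu + params.d_R - params.d_T) / (nu + rho)


def mumax_large_m(params: PTRParameters) -> float:
    """Optimized growth rate (rho(nu - d_T) - nu d_R)/(nu + rho).

    Reduces to the symmetric rho*nu/(rho + nu) when both degradation rates
    vanish, and is invariant under the simultaneous interchange
    (nu, d_T) <-> (rho, d_R).
    """
    nu, rho = params.nu, params.rho
    if nu + rho <= 0:
        raise ValueError("nu + rho must be positive")
    return (rho * (nu - params.d_T) - nu * params.d_R) / (nu + rho)


def optimum_observables_large_m(params: PTRParameters) -> tuple:
    """(Phi_R, T/R) at the large-m optimum: nu/(nu+rho), (m_R/m_T)(rho/nu).

    Both are independent of the degradation rates.
    """
    nu, rho = params.nu, params.rho
    if nu == 0:
        raise ValueError("T/R undefined at nu = 0")
    return nu / (nu + rho), (params.m_R / params.m_T) * (rho / nu)


def large_m_optimum(params: PTRParameters) -> OptimumResult:
    """Closed-form optimum bundle, with out-of-range values clamped+flagged."""
    flags = []
    f_max = fmax_large_m(params)
    if not 0.0 <= f_max <= 1.0:
        flags.append("f_max outside [0,1]: boundary optimum, formula invalid")
        f_max = min(max(f_max, 0.0), 1.0)
    mu_max = mumax_large_m(params)
    if mu_max < 0:
        flags.append("negative mu_max: non-growing optimum")
    Phi_R, T_over_R = optimum_observables_large_m(params)
    econ = economy_residual(params, T_over_R)
    return OptimumResult(f_max=f_max, mu_max=mu_max, Phi_R_opt=Phi_R,
                         T_over_R_opt=T_over_R, method="large_m",
                         economy_residual=econ, flags=tuple(flags))
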
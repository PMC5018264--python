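"""Model extensions: the constant-fraction Q sector and the linearized
three-population model.

Q sector -- a protein class occupying a fixed proteome fraction Phi_Q,
independent of growth rate.  Its production takes allocation f_Q, so the
tunable ribosomal allocation ranges over [0, 1 - f_Q].  For zero degradation
the optimized state has the closed forms

    f_R = nu (1 - f_Q) / (nu + rho),  mu = rho f_R,  Phi_R = f_R,
    Phi_R_max = 1 - f_Q,  kappa_n = nu (1 - f_Q),

with Phi_R_min and kappa_t unchanged from the three-pool model.

Linear model -- neglecting the T and R contributions to the volume
(V ~ v_P P) makes the dynamics linear, dX/dt = A X with triangular A whose
eigenvalues are {0, -d_T, b}, b = rho f_R - d_R.  The growth rate is b, the
eigenvector fixes T/R and P/R, and requiring P >= 0 gives the constraint
a >= b whose saturation a = b reproduces the large-m optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .parameters import PTRParameters, QSectorParameters
from . import model as mdl
from .growth_laws import UnsupportedCaseError


@dataclass(frozen=True)
class QSectorOptimum:
    f_R: float
    mu: float
    Phi_R: float
    Phi_Q: float
    Phi_R_max: float
    kappa_n: float


@dataclass(frozen=True)
class LinearModelResult:
    matrix: np.ndarray
    eigenvalues: tuple  # (0, -d_T, b), closed form of the triangular matrix
    growth_rate: float  # b = rho f_R - d_R
    T_over_R: float
    P_over_R: float
    feasible: bool  # a >= b, i.e. P >= 0 in the eigenvector
    flags: tuple = ()


def q_sector_optimum(params: QSectorParameters) -> QSectorOptimum:
    """Closed-form optimized steady state with a Q sector (zero degradation).

    With d_T = d_R = 0 the proteome fractions equal the allocations, so
    Phi_Q = f_Q and Phi_R = f_R at every steady state; the optimum puts
    f_R = nu (1 - f_Q)/(nu + rho) and grows at mu = rho f_R.
    """
    if params.d_T != 0.0 or params.d_R != 0.0:
        raise UnsupportedCaseError(
            "Q-sector closed forms are derived for d_T = d_R = 0 only")
    nu, rho = params.nu, params.rho
    if nu + rho <= 0:
        raise ValueError("nu + rho must be positive")
    f_R = nu * (1.0 - params.f_Q) / (nu + rho)
    mu = rho * f_R
    return QSectorOptimum(f_R=f_R, mu=mu, Phi_R=f_R, Phi_Q=params.f_Q,
                          Phi_R_max=1.0 - params.f_Q,
                          kappa_n=nu * (1.0 - params.f_Q))


def simulate_q_sector(initial: mdl.CellState, params: QSectorParameters,
                      t_end: float, **options) -> mdl.Trajectory:
    """Integrate the four-population model (P, T, R, Q).

    Same integrator contract as :func:`ptrcell.model.simulate`; the initial
    state must carry a (nonnegative) Q population.
    """
    if initial.Q is None:
        raise ValueError("initial state must include Q (use Q=0.0 to start empty)")
    return mdl.simulate(initial, params, t_end, **options)


def proteome_fractions(traj: mdl.Trajectory) -> dict:
    """Protein mass fractions Phi_T, Phi_R (and Phi_Q) along a trajectory."""
    p = traj.params
    mass = p.m_T * traj.T + p.m_R * traj.R
    out = {}
    if traj.Q is not None:
        mass = mass + p.m_Q * traj.Q
        out["Phi_Q"] = p.m_Q * traj.Q / mass
    out["Phi_T"] = p.m_T * traj.T / mass
    out["Phi_R"] = p.m_R * traj.R / mass
    return out


def q_sector_optimum_numeric(params: QSectorParameters, *, n_grid: int = 12,
                             growth_time: float = 25.0,
                             rtol: float = 1e-8) -> QSectorOptimum:
    """Cross-check of the Q-sector optimum by simulating the 4-species ODE.

    For each candidate f_R the growth rate is extracted from the tail
    log-slope of a trajectory; a coarse grid seeds a bounded scalar
    maximization.  ``growth_time`` is the integration horizon in units of
    the closed-form doubling scale 1/mu*, long enough for the transient to
    decay below the slope-fit tolerance.
    """
    closed = q_sector_optimum(params)
    t_end = growth_time / closed.mu

    def mu_of(f_R: float) -> float:
        p = params.replace(f_R=float(f_R))
        traj = simulate_q_sector(mdl.default_initial_state(p), p, t_end,
                                 rtol=rtol)
        return mdl.estimate_growth_rate(traj).mu_hat

    hi = 1.0 - params.f_Q
    grid = np.linspace(0.0, hi, n_grid + 2)[1:-1]
    mu_grid = np.array([mu_of(f) for f in grid])
    i = int(np.argmax(mu_grid))
    lo_b = grid[i - 1] if i > 0 else grid[0] / 2
    hi_b = grid[i + 1] if i < len(grid) - 1 else (grid[-1] + hi) / 2
    res = minimize_scalar(lambda f: -mu_of(f), bounds=(lo_b, hi_b),
                          method="bounded", options={"xatol": 1e-4})
    f_R, mu = float(res.x), float(-res.fun)
    if mu_grid[i] > mu:
        f_R, mu = float(grid[i]), float(mu_grid[i])
    p = params.replace(f_R=f_R)
    traj = simulate_q_sector(mdl.default_initial_state(p), p, t_end, rtol=rtol)
    fr = proteome_fractions(traj)
    return QSectorOptimum(f_R=f_R, mu=mu, Phi_R=float(fr["Phi_R"][-1]),
                          Phi_Q=float(fr["Phi_Q"][-1]),
                          Phi_R_max=1.0 - params.f_Q,
                          kappa_n=params.nu * (1.0 - params.f_Q))


def linear_model(params: PTRParameters) -> LinearModelResult:
    """Linearized dynamics in the V ~ v_P P approximation.

    The matrix is triangular up to permutation, so the spectrum
    {0, -d_T, b} is written down exactly rather than computed numerically.
    The b-eigenvector gives T = K_T R / (v_P (b + d_T)) and
    P = (k/(v_P b)) (nu f_T/(b + d_T) - 1) R; P >= 0 requires a >= b.  The
    approximation is meaningful for f_R below the optimum; beyond it P turns
    negative although the full model remains well behaved.
    """
    nu = params.nu
    a = nu * params.f_T - params.d_T
    b = params.rho * params.f_R - params.d_R
    A = np.array([[0.0, params.K_P, -params.k / params.v_P],
                  [0.0, -params.d_T, params.K_T / params.v_P],
                  [0.0, 0.0, b]])
    flags = []
    T_over_R = params.K_T / (params.v_P * (b + params.d_T)) \
        if b + params.d_T != 0 else math.nan
    if b == 0.0:
        P_over_R = math.nan
        flags.append("b = 0: P component of the eigenvector undefined")
    else:
        P_over_R = (params.k / (params.v_P * b)) \
            * (nu * params.f_T / (b + params.d_T) - 1.0)
    # a = b is the binding optimum; tolerate rounding at the boundary
    feasible = (a - b) >= -1e-12 * max(abs(a), abs(b), 1.0)
    return LinearModelResult(matrix=A, eigenvalues=(0.0, -params.d_T, b),
                             growth_rate=b, T_over_R=T_over_R,
                             P_over_R=P_over_R, feasible=feasible,
                             flags=tuple(flags))
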
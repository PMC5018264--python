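"""Dynamics of the PTR cell: volume law, ODE right-hand side, time
integration and empirical growth-rate extraction.

The population equations (counts, not concentrations) are

    dP/dt = K_P T - k R P / V
    dT/dt = K_T R P / V - d_T T
    dR/dt = K_R R P / V - d_R R
    (Q sector, optional:  dQ/dt = K_Q R P / V)

with the cell volume a linear function of the populations,
``V = v_P P + v_T T + v_R R (+ v_Q Q)``.  Because the equations are written
for populations there is no dilution term; balanced exponential growth shows
up as all populations growing with a common rate mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import PTRParameters, QSectorParameters


class SingularStateError(ValueError):
    """Raised when the right-hand side is evaluated at V = 0 with R*P > 0."""


class SimulationError(RuntimeError):
    """Integrator failure; carries the last successfully computed state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass(frozen=True)
class CellState:
    """Molecule counts of one cell (or pooled culture) at time ``t``."""

    P: float
    T: float
    R: float
    t: float = 0.0
    Q: Optional[float] = None


@dataclass
class Trajectory:
    """Solution of the population ODEs on a time grid.

    ``Q`` is ``None`` for the plain three-pool model.
    """

    t: np.ndarray
    P: np.ndarray
    T: np.ndarray
    R: np.ndarray
    params: PTRParameters
    Q: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def species(self) -> dict:
        out = {"P": self.P, "T": self.T, "R": self.R}
        if self.Q is not None:
            out["Q"] = self.Q
        return out

    def volumes(self) -> np.ndarray:
        p = self.params
        V = p.v_P * self.P + p.v_T * self.T + p.v_R * self.R
        if self.Q is not None:
            V = V + getattr(p, "v_Q", 0.0) * self.Q
        return V

    def as_frame(self) -> pd.DataFrame:
        data = {"t": self.t, **self.species(), "V": self.volumes()}
        return pd.DataFrame(data)


@dataclass(frozen=True)
class GrowthRateFit:
    """Least-squares log-slope estimate of the balanced growth rate."""

    mu_hat: float
    slopes: dict
    max_discrepancy: float
    converged: bool
    window: tuple
    n_points: int


def volume(state: CellState, params: PTRParameters) -> float:
    """Cell volume V = v_P P + v_T T + v_R R (+ v_Q Q), in um^3."""
    pops = [state.P, state.T, state.R] + ([state.Q] if state.Q is not None else [])
    for x in pops:
        if not np.isfinite(x) or x < 0:
            raise ValueError(f"populations must be finite and nonnegative, got {pops}")
    V = params.v_P * state.P + params.v_T * state.T + params.v_R * state.R
    if state.Q is not None:
        V += getattr(params, "v_Q", 0.0) * state.Q
    return V


def rhs(state: CellState, params: PTRParameters) -> tuple:
    """Time derivatives (dP/dt, dT/dt, dR/dt[, dQ/dt]) at ``state``.

    The precursor consumption flux k R P / V is split between the sectors:
    m_T*(dT/dt + d_T T) + m_R*(dR/dt + d_R R) [+ m_Q dQ/dt] recovers it
    exactly, which is the bookkeeping contract tested on every step.
    """
    V = volume(state, params)
    if V <= 0.0:
        if state.R * state.P > 0:
            raise SingularStateError("V = 0 with R*P > 0: flux singular")
        synth = 0.0
    else:
        synth = state.R * state.P / V
    dP = params.K_P * state.T - params.k * synth
    dT = params.K_T * synth - params.d_T * state.T
    dR = params.K_R * synth - params.d_R * state.R
    if state.Q is None:
        return (dP, dT, dR)
    dQ = getattr(params, "K_Q", 0.0) * synth
    return (dP, dT, dR, dQ)


def _make_rhs(params: PTRParameters, with_q: bool):
    K_P, k = params.K_P, params.k
    K_T, K_R = params.K_T, params.K_R
    d_T, d_R = params.d_T, params.d_R
    if with_q:
        vols = np.array([params.v_P, params.v_T, params.v_R, params.v_Q])
        K_Q = params.K_Q

        def fun(t, y):
            V = vols @ y
            synth = y[2] * y[0] / V
            return [K_P * y[1] - k * synth,
                    K_T * synth - d_T * y[1],
                    K_R * synth - d_R * y[2],
                    K_Q * synth]
    else:
        vols = np.array([params.v_P, params.v_T, params.v_R])

        def fun(t, y):
            V = vols @ y
            synth = y[2] * y[0] / V
            return [K_P * y[1] - k * synth,
                    K_T * synth - d_T * y[1],
                    K_R * synth - d_R * y[2]]
    return fun


def simulate(initial: CellState, params: PTRParameters, t_end: float, *,
             rtol: float = 1e-8, atol_scale: float = 1e-12,
             method: str = "LSODA", n_points: int = 256) -> Trajectory:
    """Integrate the population ODEs from ``initial`` to ``t_end``.

    A stiff-capable adaptive method is used because the initial relaxation
    of the precursor pool is much faster than the growth timescale.  The
    per-species absolute tolerance is ``atol_scale`` times the initial
    population, so that species four orders of magnitude apart (m_R = 1e4)
    are resolved comparably.  Populations are never clipped.
    """
    with_q = initial.Q is not None
    if with_q and not isinstance(params, QSectorParameters):
        raise TypeError("Q-sector initial state requires QSectorParameters")
    y0 = [initial.P, initial.T, initial.R] + ([initial.Q] if with_q else [])
    if min(y0[:3]) <= 0:
        raise ValueError("initial P, T, R must be positive")
    if with_q and y0[3] < 0:
        raise ValueError("initial Q must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    atol = np.array([max(y, 1.0) * atol_scale for y in y0])
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(_make_rhs(params, with_q), (0.0, t_end), y0,
                    method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}",
                              last_time=float(sol.t[-1]) if sol.t.size else 0.0,
                              last_state=sol.y[:, -1] if sol.t.size else np.array(y0))
    meta = {"method": method, "rtol": rtol, "atol_scale": atol_scale,
            "t_end": t_end, "n_points": n_points}
    return Trajectory(t=sol.t, P=sol.y[0], T=sol.y[1], R=sol.y[2],
                      Q=sol.y[3] if with_q else None, params=params, meta=meta)


def estimate_growth_rate(traj: Trajectory,
                         tail_fraction: float = 0.25) -> GrowthRateFit:
    """Estimate the balanced growth rate from the tail of a trajectory.

    Fits log-population against time by ordinary least squares on the last
    ``tail_fraction`` of the time span, per species, and pools the slopes by
    averaging.  The maximum pairwise slope discrepancy is the convergence
    diagnostic; balanced growth is declared below 1e-4 /hr.

    Species that are identically zero along the whole trajectory (e.g. a Q
    sector started empty with f_Q = 0) are excluded; any other nonpositive
    tail value is an error.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    t = traj.t
    span = t[-1] - t[0]
    t0 = t[-1] - tail_fraction * span
    mask = t >= t0
    if mask.sum() < 10:
        raise ValueError(f"tail window has {int(mask.sum())} points; need >= 10")
    tt = t[mask]
    slopes = {}
    for name, pop in traj.species().items():
        if np.all(pop == 0.0):
            continue
        tail = pop[mask]
        if np.any(tail <= 0):
            raise ValueError(f"nonpositive {name} values in tail window")
        slopes[name] = float(np.polyfit(tt, np.log(tail), 1)[0])
    if not slopes:
        raise ValueError("no nonzero species to fit")
    vals = list(slopes.values())
    disc = max(abs(a - b) for a in vals for b in vals)
    return GrowthRateFit(mu_hat=float(np.mean(vals)), slopes=slopes,
                         max_discrepancy=disc, converged=disc < 1e-4,
                         window=(float(tt[0]), float(tt[-1])),
                         n_points=int(mask.sum()))


def default_initial_state(params: PTRParameters) -> CellState:
    """Default starting populations: P = 10*m_R, T = R = 10.

    The model is scale invariant (multiplying all populations by c > 0
    rescales the trajectory without changing rates or ratios), so the choice
    only sets the transient.
    """
    q0 = 0.0 if isinstance(params, QSectorParameters) else None
    return CellState(P=10.0 * params.m_R, T=10.0, R=10.0, t=0.0, Q=q0)
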
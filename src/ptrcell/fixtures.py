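"""Random valid parameter sets for testing and batch exploration.

Rates, sizes and volumes are drawn log-uniformly (they are positive scale
parameters spanning decades); degradation rates and the allocation fraction
are drawn uniformly since zero is a meaningful endpoint.  When growing
steady states are required, sets are rejection-sampled until the physical
root mu_- is positive and the balanced ratios are feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .parameters import PTRParameters
from . import steady_state as sstate

#: parameters sampled log-uniformly; all others uniformly
_LOG_PARAMS = {"K_P", "k", "m_T", "m_R", "v_P"}

#: ranges bracketing a realistic enteric-bacterium regime
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "K_P": (50.0, 1000.0),
    "k": (1e-4, 2e-3),
    "m_T": (100.0, 2000.0),
    "m_R": (2e3, 5e4),
    "v_P": (5e-9, 2e-8),
    "v_T": (0.0, 2e-8),
    "v_R": (0.0, 2e-8),
    "d_T": (0.0, 0.2),
    "d_R": (0.0, 0.02),
    "f_R": (0.02, 0.6),
}


class InfeasibleSpecError(RuntimeError):
    """The requested ranges never produce a growing parameter set."""


@dataclass(frozen=True)
class FixtureSpec:
    n_sets: int
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    require_growth: bool = True
    seed: int = 0
    max_rejections: int = 10_000


@dataclass(frozen=True)
class FixtureBatch:
    parameter_sets: List[PTRParameters]
    n_rejected: int

    @property
    def rejection_rate(self) -> float:
        total = len(self.parameter_sets) + self.n_rejected
        return self.n_rejected / total if total else 0.0


def _sample_one(rng: np.random.Generator,
                ranges: Dict[str, Tuple[float, float]]) -> PTRParameters:
    fields = {}
    for name, (lo, hi) in ranges.items():
        if name in _LOG_PARAMS:
            fields[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            fields[name] = float(rng.uniform(lo, hi))
    return PTRParameters(**fields)


def generate_fixtures(spec: FixtureSpec) -> FixtureBatch:
    """Seeded, reproducible batch of valid parameter sets.

    With ``require_growth`` each set must have mu_- > 0 and a feasible
    balanced state; more than ``max_rejections`` consecutive failures raise
    :class:`InfeasibleSpecError`.
    """
    ranges = dict(DEFAULT_RANGES)
    ranges.update(spec.ranges)
    for name, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if name in _LOG_PARAMS and lo <= 0:
            raise ValueError(f"log-sampled {name} requires a positive range")
    rng = np.random.default_rng(spec.seed)
    sets: List[PTRParameters] = []
    rejected = 0
    consecutive = 0
    while len(sets) < spec.n_sets:
        params = _sample_one(rng, ranges)
        if spec.require_growth:
            ss = sstate.balanced_state(params)
            if not (ss.feasible and ss.mu > 0):
                rejected += 1
                consecutive += 1
                if consecutive > spec.max_rejections:
                    raise InfeasibleSpecError(
                        f"{consecutive} consecutive rejections; ranges admit "
                        "no growing steady state")
                continue
        consecutive = 0
        sets.append(params)
    return FixtureBatch(parameter_sets=sets, n_rejected=rejected)
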
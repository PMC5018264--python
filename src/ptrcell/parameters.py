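"""Parameter containers for the precursor-transporter-ribosome (PTR) cell.

The PTR cell is a coarse-grained model of a growing bacterium with three
molecular pools: a precursor (amino-acid) pool ``P``, metabolic/transport
enzymes ``T`` that import food and convert it into precursor, and ribosomes
``R`` that synthesize both ``T`` and themselves from the precursor pool.
A fraction ``f_R`` of ribosomes makes ribosomal protein and the remaining
``f_T = 1 - f_R`` makes metabolic protein.

Units are fixed throughout the package: rates in 1/hr, molecular volumes in
cubic micrometres.  There is no unit-conversion layer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class PTRParameters:
    """Rate, size and allocation constants of the PTR cell.

    Attributes
    ----------
    K_P:
        Precursor production rate per transporter molecule (1/hr).  Encodes
        both food concentration and food quality.
    k:
        Ribosome catalytic efficiency (hr^-1 um^3): rate at which one
        ribosome consumes precursor per unit precursor concentration.
    m_T, m_R:
        Amino-acid residues per transporter / per ribosome (counts >= 1).
    d_T, d_R:
        Degradation rates of T and R (1/hr, >= 0).  The precursor pool is
        assumed not to degrade.
    v_P, v_T, v_R:
        Molecular volumes (um^3); cell volume is V = v_P P + v_T T + v_R R.
        ``v_P`` must be strictly positive.
    f_R:
        Fraction of ribosomes allocated to making ribosomal protein,
        in [0, 1].
    """

    K_P: float
    k: float
    m_T: float
    m_R: float
    d_T: float = 0.0
    d_R: float = 0.0
    v_P: float = 1e-8
    v_T: float = 0.0
    v_R: float = 0.0
    f_R: float = 0.5

    def __post_init__(self) -> None:
        for name in ("K_P", "k", "m_T", "m_R", "d_T", "d_R",
                     "v_P", "v_T", "v_R", "f_R"):
            value = getattr(self, name)
            _require(math.isfinite(value), f"{name} must be finite, got {value!r}")
        _require(self.K_P >= 0, "K_P must be nonnegative")
        _require(self.k >= 0, "k must be nonnegative")
        _require(self.m_T >= 1, "m_T must be >= 1")
        _require(self.m_R >= 1, "m_R must be >= 1")
        _require(self.d_T >= 0, "d_T must be nonnegative")
        _require(self.d_R >= 0, "d_R must be nonnegative")
        _require(self.v_P > 0, "v_P must be strictly positive")
        _require(self.v_T >= 0, "v_T must be nonnegative")
        _require(self.v_R >= 0, "v_R must be nonnegative")
        _require(0.0 <= self.f_R <= 1.0, "f_R must lie in [0, 1]")

    # -- allocation ---------------------------------------------------------

    @property
    def f_T(self) -> float:
        """Fraction of ribosomes making metabolic protein, 1 - f_R."""
        return 1.0 - self.f_R

    @property
    def K_T(self) -> float:
        """Transporter production rate constant, f_T * k / m_T."""
        return self.f_T * self.k / self.m_T

    @property
    def K_R(self) -> float:
        """Ribosome production rate constant, f_R * k / m_R."""
        return self.f_R * self.k / self.m_R

    # -- efficiencies -------------------------------------------------------

    @property
    def nu(self) -> float:
        """Nutritional efficiency: precursor produced per hour per residue
        invested in metabolic enzymes, K_P / m_T."""
        return self.K_P / self.m_T

    @property
    def rho(self) -> float:
        """Ribosomal (translational) efficiency: maximal self-replication
        rate of the ribosome pool, k / (m_R * v_P)."""
        return self.k / (self.m_R * self.v_P)

    def replace(self, **changes) -> "PTRParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class QSectorParameters(PTRParameters):
    """PTR parameters extended with a constant-fraction protein sector Q.

    The Q sector occupies a fixed allocation ``f_Q`` so that
    ``f_T + f_R + f_Q = 1`` with ``f_T = 1 - f_R - f_Q``; the cell volume
    gains a term ``v_Q * Q``.
    """

    f_Q: float = 0.0
    m_Q: float = 1.0
    v_Q: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        _require(math.isfinite(self.f_Q) and 0.0 <= self.f_Q < 1.0,
                 "f_Q must lie in [0, 1)")
        _require(self.f_R <= 1.0 - self.f_Q + 1e-15,
                 "f_R must not exceed 1 - f_Q")
        _require(self.m_Q >= 1, "m_Q must be >= 1")
        _require(self.v_Q >= 0, "v_Q must be nonnegative")

    @property
    def f_T(self) -> float:
        return 1.0 - self.f_R - self.f_Q

    @property
    def K_Q(self) -> float:
        """Q-sector production rate constant, f_Q * k / m_Q."""
        return self.f_Q * self.k / self.m_Q


def baseline_parameters(q: float = 1.0, f_R: float = 0.1,
                        **overrides) -> PTRParameters:
    """A representative E. coli-like parameter set.

    ``K_P = q * k_P`` with ``k_P = 250 /hr``; medium quality ``q`` scales the
    precursor yield per food molecule.  With the defaults the efficiencies
    are nu = 0.5*q /hr and rho = 5 /hr.
    """
    fields = dict(K_P=q * 250.0, k=5e-4, m_T=500.0, m_R=1e4,
                  d_T=0.1, d_R=0.0, v_P=1e-8, v_T=1e-8, v_R=1e-8, f_R=f_R)
    fields.update(overrides)
    return PTRParameters(**fields)
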
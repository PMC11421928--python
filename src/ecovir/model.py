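"""Core model: domain types, trade-offs, specialism mapping and ODE right-hand sides.

Model structure
---------------
Two host types (1 and 2) share a single horizontally transmitted parasite in
an SIS framework.  Densities of susceptible and infected hosts of type *i* are
``Si`` and ``Ii``, with ``Ni = Si + Ii`` (plus mutant-infected hosts when a
rare mutant strain is present).  Hosts reproduce only while susceptible, at a
crowding-limited per-capita rate ``b(1 - q*Ni)`` that is additionally modified
by the other host through a signed interaction term ``rij * Nj * Si``
(competition ``rij < 0``, mutualism ``rij > 0``, exploitation when the two
coefficients have opposite signs).

Transmission is decomposed into a host-controlled susceptibility factor
``betaS_i`` and a parasite-controlled onward-transmission factor ``betaT_j``
so the infection pressure on host *i* from infections in host *j* is
``betaS_i * betaT_j * Si * Ij`` (inter- and intra-host contact rates are set
equal and absorbed into ``betaS_i``).

The evolving parasite trait is the intra-host growth rate ``epsilon``.  It
drives two life-history trade-offs:

* virulence (disease-induced mortality): ``alpha_i = f(epsilon_i)``, with the
  identity ``f(e) = e`` as the default;
* onward transmission: ``betaT_i = c * epsilon_i ** eta`` with ``0 < eta < 1``
  (saturating transmission returns on faster growth).

Specialism cases map the single evolving trait to per-host phenotypes; see
:func:`phenotype_from_trait`.

Naming note: the trade-off exponent (``< 1``) is called ``eta`` here and the
recovery rate ``gamma_rec``, because the conventional symbol ``gamma`` is used
for both in the literature this model comes from.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "EcoParams",
    "SpecialismCase",
    "PreferredHost",
    "SpecialismSpec",
    "ParasiteStrain",
    "SystemState",
    "phenotype_from_trait",
    "resident_rhs",
    "resident_mutant_rhs",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True)
class EcoParams:
    """Ecological and epidemiological rate constants shared by both hosts.

    Parameters
    ----------
    b : float
        Per-capita birth rate of susceptible hosts (1/time).  Must exceed ``d``.
    d : float
        Natural (background) death rate (1/time).
    q : float
        Intraspecific crowding coefficient (1/density); the disease-free
        carrying density is ``(b - d) / (b * q)``.
    gamma_rec : float
        Recovery rate from infection (1/time); recovered hosts return to the
        susceptible class (SIS).
    r12, r21 : float
        Signed effect of host 2 on host 1's birth rate and vice versa
        (1/(density*time)).  Matching signs give mutualism (+/+) or
        competition (-/-); opposite signs give exploitation.
    c : float
        Scale constant of the transmission trade-off ``betaT = c * eps**eta``.
    eta : float
        Trade-off exponent, ``0 < eta < 1`` (diminishing transmission returns).
    """

    b: float = 4.0
    d: float = 1.0
    q: float = 1e-3
    gamma_rec: float = 0.5
    r12: float = 0.0
    r21: float = 0.0
    c: float = 0.01
    eta: float = 0.5

    def __post_init__(self) -> None:
        if not (self.b > self.d > 0):
            raise ValueError(f"require b > d > 0, got b={self.b}, d={self.d}")
        if self.q <= 0:
            raise ValueError(f"crowding coefficient q must be > 0, got {self.q}")
        if self.gamma_rec < 0:
            raise ValueError(f"recovery rate must be >= 0, got {self.gamma_rec}")
        if self.c <= 0:
            raise ValueError(f"trade-off constant c must be > 0, got {self.c}")
        if not (0 < self.eta < 1):
            raise ValueError(f"trade-off exponent eta must lie in (0, 1), got {self.eta}")
        for name in ("r12", "r21"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def disease_free_density(self) -> float:
        """Single-host carrying density ``(b - d)/(b q)`` with no parasite, no partner."""
        return (self.b - self.d) / (self.b * self.q)

    def with_interactions(self, r12: float, r21: float) -> "EcoParams":
        """Copy of the parameter set with the interaction coefficients replaced."""
        return replace(self, r12=r12, r21=r21)


#: Package-wide default parameterization.  The trade-off scale ``c`` is chosen
#: so endemic host densities are of order 100 (disease-free density 750),
#: which makes interaction coefficients of magnitude ~1e-4..3e-4 ecologically
#: meaningful perturbations.
DEFAULT_PARAMS = EcoParams()


class SpecialismCase(enum.Enum):
    """Mechanism by which the parasite performs better on its preferred host (PH)."""

    GENERALIST = "generalist"
    #: PH is more susceptible to initial infection (higher betaS).
    CASE1_SUSCEPTIBILITY = "case1_susceptibility"
    #: PH sustains a faster intra-host growth rate (higher realized epsilon,
    #: hence higher virulence and transmission there).
    CASE2_GROWTH = "case2_growth"
    #: parasite transmits onward more effectively from the PH (higher betaT).
    CASE3_TRANSMISSION = "case3_transmission"
    #: PH tolerates infection (lower virulence there; "tolerance").
    CASE4_TOLERANCE = "case4_tolerance"


class PreferredHost(enum.Enum):
    HOST1 = 1
    HOST2 = 2

    @property
    def index(self) -> int:
        """Zero-based index of the preferred host."""
        return self.value - 1


@dataclass(frozen=True)
class SpecialismSpec:
    """A specialism mechanism together with its dimensionless strength ``s in [0, 1)``.

    ``strength = 0`` always reduces to the generalist; ``GENERALIST`` forces it.
    """

    case_id: SpecialismCase = SpecialismCase.GENERALIST
    strength: float = 0.0
    preferred_host: PreferredHost = PreferredHost.HOST1

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength < 1.0):
            raise ValueError(f"specialism strength must lie in [0, 1), got {self.strength}")
        if self.case_id is SpecialismCase.GENERALIST and self.strength != 0.0:
            raise ValueError("GENERALIST requires strength = 0")

    def swapped(self) -> "SpecialismSpec":
        """Same mechanism with the preferred-host label exchanged."""
        other = (
            PreferredHost.HOST2
            if self.preferred_host is PreferredHost.HOST1
            else PreferredHost.HOST1
        )
        return SpecialismSpec(self.case_id, self.strength, other)


@dataclass(frozen=True)
class ParasiteStrain:
    """Realized per-host phenotype of one parasite strain.

    ``epsilon`` is the evolving scalar (intrinsic growth-rate trait); the
    tuples hold the realized per-host values ``(host 1, host 2)`` after the
    specialism mapping and trade-offs have been applied.
    """

    epsilon: float
    beta_s: Tuple[float, float]
    beta_t: Tuple[float, float]
    alpha: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if any(v < 0 for v in self.beta_s + self.beta_t + self.alpha):
            raise ValueError("phenotype components must be non-negative")


@dataclass(frozen=True)
class SystemState:
    """Compartment densities; mutant-infected classes optional (default absent)."""

    s1: float
    i1: float
    s2: float
    i2: float
    i1m: Optional[float] = None
    i2m: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("s1", "i1", "s2", "i2"):
            if getattr(self, name) < 0:
                raise ValueError(f"compartment {name} must be non-negative")
        for name in ("i1m", "i2m"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"compartment {name} must be non-negative")
        if (self.i1m is None) != (self.i2m is None):
            raise ValueError("provide both mutant compartments or neither")

    @property
    def has_mutant(self) -> bool:
        return self.i1m is not None

    @property
    def n1(self) -> float:
        return self.s1 + self.i1 + (self.i1m or 0.0)

    @property
    def n2(self) -> float:
        return self.s2 + self.i2 + (self.i2m or 0.0)

    def to_array(self) -> np.ndarray:
        if self.has_mutant:
            return np.array([self.s1, self.i1, self.s2, self.i2, self.i1m, self.i2m])
        return np.array([self.s1, self.i1, self.s2, self.i2])

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SystemState":
        y = list(map(float, y))
        if len(y) == 4:
            return cls(*y)
        if len(y) == 6:
            return cls(*y)
        raise ValueError("state vector must have length 4 or 6")


# --------------------------------------------------------------------------
# trait -> phenotype mapping
# --------------------------------------------------------------------------

def _transmission(eps: float, params: EcoParams, eta: Optional[float] = None) -> float:
    """Saturating transmission trade-off ``betaT = c * eps**eta``."""
    e = params.eta if eta is None else eta
    return params.c * eps ** e


def phenotype_from_trait(
    epsilon: float,
    spec: SpecialismSpec,
    params: EcoParams,
    virulence_fn: Callable[[float], float] = lambda e: e,
) -> ParasiteStrain:
    """Map the evolving growth-rate trait to a realized per-host phenotype.

    The baseline (generalist) phenotype is ``betaS = 1`` for both hosts,
    ``alpha = virulence_fn(epsilon)`` (identity by default) and
    ``betaT = c * epsilon**eta``.  With specialism strength ``s`` and the
    preferred host PH (non-preferred NPH):

    * ``CASE1_SUSCEPTIBILITY``: ``betaS_PH = 1 + s``, ``betaS_NPH = 1 - s``;
      growth, virulence and transmission stay symmetric.
    * ``CASE2_GROWTH``: the realized growth rate is ``epsilon`` on the PH and
      ``(1 - s) * epsilon`` on the NPH; virulence and transmission follow each
      host's realized growth rate through the trade-offs.
    * ``CASE3_TRANSMISSION``: equal growth and virulence on both hosts, but
      the PH transmission curve is elevated, ``betaT_PH = (1+s) c eps**eta``,
      while the NPH curve is both lowered and flattened,
      ``betaT_NPH = (1-s) c eps**(eta (1-s))`` — specialism degrades how much
      the NPH converts extra parasite growth into onward transmission, not
      just the overall amount.
    * ``CASE4_TOLERANCE``: equal growth and transmission, but virulence is
      ``(1 - s) * alpha`` on the (tolerant) PH and ``(1 + s) * alpha`` on the
      NPH.

    At ``s = 0`` every case collapses to the generalist.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    s = spec.strength
    ph = spec.preferred_host.index  # 0 or 1
    nph = 1 - ph

    beta_s = [1.0, 1.0]
    eps_host = [epsilon, epsilon]
    beta_t = [None, None]
    alpha = [None, None]

    case = spec.case_id
    if case is SpecialismCase.CASE1_SUSCEPTIBILITY:
        beta_s[ph] = 1.0 + s
        beta_s[nph] = 1.0 - s
    elif case is SpecialismCase.CASE2_GROWTH:
        eps_host[nph] = (1.0 - s) * epsilon
    # realized virulence and transmission from the (possibly host-specific)
    # realized growth rates
    for i in (0, 1):
        alpha[i] = virulence_fn(eps_host[i])
        beta_t[i] = _transmission(eps_host[i], params)

    if case is SpecialismCase.CASE3_TRANSMISSION:
        beta_t[ph] = (1.0 + s) * _transmission(epsilon, params)
        beta_t[nph] = (1.0 - s) * _transmission(epsilon, params, eta=params.eta * (1.0 - s))
    elif case is SpecialismCase.CASE4_TOLERANCE:
        alpha[ph] = (1.0 - s) * virulence_fn(epsilon)
        alpha[nph] = (1.0 + s) * virulence_fn(epsilon)

    return ParasiteStrain(
        epsilon=epsilon,
        beta_s=(beta_s[0], beta_s[1]),
        beta_t=(beta_t[0], beta_t[1]),
        alpha=(alpha[0], alpha[1]),
    )


# --------------------------------------------------------------------------
# ODE right-hand sides
# --------------------------------------------------------------------------

def _rhs4(y: np.ndarray, strain: ParasiteStrain, params: EcoParams) -> np.ndarray:
    """Resident-only right-hand side on a raw length-4 array (solver kernel)."""
    s1, i1, s2, i2 = y
    n1 = s1 + i1
    n2 = s2 + i2
    bs1, bs2 = strain.beta_s
    bt1, bt2 = strain.beta_t
    a1, a2 = strain.alpha
    p = params
    lam1 = bs1 * (bt1 * i1 + bt2 * i2)  # force of infection on host 1
    lam2 = bs2 * (bt2 * i2 + bt1 * i1)
    ds1 = p.b * (1 - p.q * n1) * s1 - p.d * s1 + p.r12 * n2 * s1 - lam1 * s1 + p.gamma_rec * i1
    di1 = lam1 * s1 - p.gamma_rec * i1 - (p.d + a1) * i1
    ds2 = p.b * (1 - p.q * n2) * s2 - p.d * s2 + p.r21 * n1 * s2 - lam2 * s2 + p.gamma_rec * i2
    di2 = lam2 * s2 - p.gamma_rec * i2 - (p.d + a2) * i2
    return np.array([ds1, di1, ds2, di2])


def _rhs6(
    y: np.ndarray,
    resident: ParasiteStrain,
    mutant: ParasiteStrain,
    params: EcoParams,
) -> np.ndarray:
    """Resident + rare-mutant right-hand side on a raw length-6 array.

    Hosts carry either the resident or the mutant strain, never both.  The
    mutant-infected classes count towards the host totals ``Ni`` (so towards
    crowding and the host–host interaction terms) and recover back into the
    susceptible pool.
    """
    s1, i1, s2, i2, i1m, i2m = y
    n1 = s1 + i1 + i1m
    n2 = s2 + i2 + i2m
    bs1, bs2 = resident.beta_s
    bt1, bt2 = resident.beta_t
    a1, a2 = resident.alpha
    bs1m, bs2m = mutant.beta_s
    bt1m, bt2m = mutant.beta_t
    a1m, a2m = mutant.alpha
    p = params
    lam1 = bs1 * (bt1 * i1 + bt2 * i2)
    lam2 = bs2 * (bt2 * i2 + bt1 * i1)
    lam1m = bs1m * (bt1m * i1m + bt2m * i2m)
    lam2m = bs2m * (bt2m * i2m + bt1m * i1m)
    ds1 = (
        p.b * (1 - p.q * n1) * s1
        - p.d * s1
        + p.r12 * n2 * s1
        - (lam1 + lam1m) * s1
        + p.gamma_rec * (i1 + i1m)
    )
    di1 = lam1 * s1 - p.gamma_rec * i1 - (p.d + a1) * i1
    ds2 = (
        p.b * (1 - p.q * n2) * s2
        - p.d * s2
        + p.r21 * n1 * s2
        - (lam2 + lam2m) * s2
        + p.gamma_rec * (i2 + i2m)
    )
    di2 = lam2 * s2 - p.gamma_rec * i2 - (p.d + a2) * i2
    di1m = lam1m * s1 - p.gamma_rec * i1m - (p.d + a1m) * i1m
    di2m = lam2m * s2 - p.gamma_rec * i2m - (p.d + a2m) * i2m
    return np.array([ds1, di1, ds2, di2, di1m, di2m])


def resident_rhs(
    state: SystemState, strain: ParasiteStrain, params: EcoParams
) -> Tuple[float, float, float, float]:
    """Time derivatives ``(dS1, dI1, dS2, dI2)`` of the resident-only system."""
    if state.has_mutant:
        raise ValueError("resident_rhs expects a four-compartment state")
    out = _rhs4(state.to_array(), strain, params)
    return tuple(float(v) for v in out)


def resident_mutant_rhs(
    state: SystemState,
    resident: ParasiteStrain,
    mutant: ParasiteStrain,
    params: EcoParams,
) -> Tuple[float, float, float, float, float, float]:
    """Time derivatives of the six-compartment resident + mutant system."""
    if not state.has_mutant:
        raise ValueError("resident_mutant_rhs expects a six-compartment state")
    out = _rhs6(state.to_array(), resident, mutant, params)
    return tuple(float(v) for v in out)
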
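"""Invasion fitness, selection gradients, pairwise invasibility plots and ES virulence.

A rare mutant strain with trait ``epsM`` introduced into the resident system
at its stable endemic equilibrium ``(S1^, I1^, S2^, I2^)`` grows initially
according to the 2x2 linearization of the mutant-infected subsystem.  Because
that block has the rank-one structure ``a_ij = betaS_iM * betaT_jM * Si^``,
its dominant eigenvalue is positive exactly when

    Gamma2M * betaS1M * betaT1M * S1^
  + Gamma1M * betaS2M * betaT2M * S2^
  - Gamma1M * Gamma2M  >  0,

with mutant loss rates ``Gamma_iM = d + gamma_rec + alpha_iM``.  The signed
left-hand side is the invasion-fitness proxy used throughout this module: it
is zero for the resident in its own equilibrium, its sign is the sign of the
mutant's initial growth rate, and it only requires the resident susceptible
densities.  Singular strategies are roots of the selection gradient (the
mutant-trait derivative at the resident value), refined by bracketed root
solving and classified by second-order behaviour (evolutionary stability) and
by the gradient slope (convergence stability).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .model import EcoParams, SpecialismSpec, SystemState, phenotype_from_trait
from .equilibrium import EquilibriumClass, EquilibriumResult, find_equilibrium

__all__ = [
    "InvasionResult",
    "PipGrid",
    "EssClass",
    "EssResult",
    "invasion_fitness",
    "selection_gradient",
    "build_pip",
    "find_ess",
    "NEUTRALITY_BAND",
]

#: |fitness| below this is treated as selectively neutral in sign classifications.
NEUTRALITY_BAND = 1e-10


@dataclass(frozen=True)
class InvasionResult:
    """Signed invasion-fitness value for one (resident equilibrium, mutant) pair."""

    fitness_value: float
    gamma1m: float
    gamma2m: float

    @property
    def invadable(self) -> bool:
        return self.fitness_value > 0


class EssClass(enum.Enum):
    CSS = "css"
    ESS_NOT_CONVERGENT = "ess_not_convergent"
    BRANCHING = "branching"
    REPELLER = "repeller"


@dataclass(frozen=True)
class EssResult:
    """A singular strategy of the trait-substitution dynamics."""

    epsilon_star: float
    alpha_realized: Tuple[float, float]
    classification: EssClass
    diagnostics: Dict[str, float]
    equilibrium: EquilibriumResult

    @property
    def max_es_virulence(self) -> float:
        """Greater of the two realized virulences at the singular strategy."""
        return max(self.alpha_realized)

    def summary(self) -> str:
        a1, a2 = self.alpha_realized
        lines = [
            f"singular trait epsilon* : {self.epsilon_star:.8g}",
            f"realized alpha (host 1) : {a1:.8g}",
            f"realized alpha (host 2) : {a2:.8g}",
            f"max ES virulence        : {self.max_es_virulence:.8g}",
            f"classification          : {self.classification.value}",
            f"selection gradient      : {self.diagnostics['gradient']:.3e}",
            f"fitness curvature       : {self.diagnostics['fitness_curvature']:.3e}",
            f"gradient slope          : {self.diagnostics['gradient_slope']:.3e}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class PipGrid:
    """Sign map of invasion fitness over a (resident, mutant) trait grid.

    ``sign_matrix[i, j]`` is the sign (-1, 0, +1) of the invasion fitness of
    mutant ``trait_axis[j]`` against resident ``trait_axis[i]``; residents
    without a stable endemic equilibrium are masked (``resident_ok[i]`` False,
    row filled with 0).
    """

    trait_axis: np.ndarray
    sign_matrix: np.ndarray
    resident_ok: np.ndarray
    singular_points: Tuple[float, ...]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.sign_matrix,
            index=pd.Index(self.trait_axis, name="resident_eps"),
            columns=pd.Index(self.trait_axis, name="mutant_eps"),
        )


def invasion_fitness(
    mutant_eps: float,
    resident_eq: EquilibriumResult,
    spec: SpecialismSpec,
    params: EcoParams,
    virulence_fn: Callable[[float], float] = lambda e: e,
) -> InvasionResult:
    """Signed invasion fitness of a rare mutant in the resident's equilibrium.

    Raises if the resident equilibrium is not a stable endemic one (the
    linearization that defines invasion fitness presumes it).
    """
    if resident_eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
        raise ValueError(
            "invasion fitness requires a STABLE_ENDEMIC resident equilibrium, "
            f"got {resident_eq.classification.value}"
        )
    mut = phenotype_from_trait(mutant_eps, spec, params, virulence_fn)
    s1_hat = resident_eq.state_hat.s1
    s2_hat = resident_eq.state_hat.s2
    g1m = params.d + params.gamma_rec + mut.alpha[0]
    g2m = params.d + params.gamma_rec + mut.alpha[1]
    w = (
        g2m * mut.beta_s[0] * mut.beta_t[0] * s1_hat
        + g1m * mut.beta_s[1] * mut.beta_t[1] * s2_hat
        - g1m * g2m
    )
    return InvasionResult(float(w), g1m, g2m)


def _gradient_at(
    resident_eps: float,
    eq: EquilibriumResult,
    spec: SpecialismSpec,
    params: EcoParams,
    h: Optional[float] = None,
) -> float:
    if h is None:
        h = 1e-4 * max(resident_eps, 1.0)
    wp = invasion_fitness(resident_eps + h, eq, spec, params).fitness_value
    wm = invasion_fitness(resident_eps - h, eq, spec, params).fitness_value
    return (wp - wm) / (2.0 * h)


def selection_gradient(
    resident_eps: float,
    spec: SpecialismSpec,
    params: EcoParams,
    eq: Optional[EquilibriumResult] = None,
    h: Optional[float] = None,
) -> float:
    """Local fitness gradient: mutant-trait derivative of invasion fitness.

    Central finite difference with step ``h = 1e-4 * max(eps, 1)`` by default,
    evaluated in the resident's endemic equilibrium (solved here unless one is
    supplied).  Its sign is the direction of trait substitution.
    """
    if eq is None:
        eq = find_equilibrium(phenotype_from_trait(resident_eps, spec, params), params)
    if eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
        raise ValueError(
            f"no stable endemic equilibrium at resident eps={resident_eps} "
            f"({eq.classification.value})"
        )
    return _gradient_at(resident_eps, eq, spec, params, h)


class _ResidentEquilibria:
    """Warm-started resident-equilibrium provider used inside root solves."""

    def __init__(self, spec: SpecialismSpec, params: EcoParams,
                 init: Optional[SystemState] = None):
        self.spec = spec
        self.params = params
        self._last_state: Optional[SystemState] = init

    def __call__(self, eps: float) -> EquilibriumResult:
        strain = phenotype_from_trait(eps, self.spec, self.params)
        eq = find_equilibrium(strain, self.params, init=self._last_state)
        if eq.classification is not EquilibriumClass.STABLE_ENDEMIC and self._last_state is not None:
            # warm start may have tracked a vanishing branch: retry cold
            eq = find_equilibrium(strain, self.params)
        if eq.classification is EquilibriumClass.STABLE_ENDEMIC:
            self._last_state = eq.state_hat
        return eq


def find_ess(
    spec: SpecialismSpec,
    params: EcoParams,
    bracket: Tuple[float, float] = (0.2, 6.0),
    rtol: float = 1e-9,
    eq_init: Optional[SystemState] = None,
) -> EssResult:
    """Locate and classify the singular trait value inside ``bracket``.

    The selection gradient must change sign across the bracket; the root is
    refined with Brent's method, then classified:

    * evolutionary stability from the curvature of mutant fitness at the
      singular point (negative: no nearby mutant invades);
    * convergence stability from the slope of the selection gradient
      (negative: trait substitution walks towards the point).

    CSS means both hold.  Branching points (convergence-stable fitness
    minima) are reported as such, never silently coerced.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError(f"invalid bracket {bracket}")
    eqs = _ResidentEquilibria(spec, params, init=eq_init)

    def grad(eps: float) -> float:
        eq = eqs(eps)
        if eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
            raise ValueError(
                f"equilibrium failure inside bracket at eps={eps:.6g}: "
                f"{eq.classification.value}"
            )
        return _gradient_at(eps, eq, spec, params)

    g_lo, g_hi = grad(lo), grad(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValueError(
            f"selection gradient does not change sign on {bracket}: "
            f"D({lo})={g_lo:.3e}, D({hi})={g_hi:.3e}"
        )
    eps_star = float(brentq(grad, lo, hi, rtol=rtol, xtol=1e-12))

    eq_star = eqs(eps_star)
    strain_star = phenotype_from_trait(eps_star, spec, params)
    g_star = _gradient_at(eps_star, eq_star, spec, params)

    # evolutionary stability: curvature of w(mutant) at fixed resident
    h = 1e-3 * max(eps_star, 1.0)
    w0 = invasion_fitness(eps_star, eq_star, spec, params).fitness_value
    wp = invasion_fitness(eps_star + h, eq_star, spec, params).fitness_value
    wm = invasion_fitness(eps_star - h, eq_star, spec, params).fitness_value
    curvature = (wp - 2.0 * w0 + wm) / h**2

    # convergence stability: slope of the gradient in the resident trait
    gp = _gradient_at(eps_star + h, eqs(eps_star + h), spec, params)
    gm = _gradient_at(eps_star - h, eqs(eps_star - h), spec, params)
    grad_slope = (gp - gm) / (2.0 * h)

    es_stable = curvature < 0
    conv_stable = grad_slope < 0
    if es_stable and conv_stable:
        cls = EssClass.CSS
    elif es_stable:
        cls = EssClass.ESS_NOT_CONVERGENT
    elif conv_stable:
        cls = EssClass.BRANCHING
    else:
        cls = EssClass.REPELLER

    return EssResult(
        epsilon_star=eps_star,
        alpha_realized=strain_star.alpha,
        classification=cls,
        diagnostics={
            "gradient": float(g_star),
            "fitness_curvature": float(curvature),
            "gradient_slope": float(grad_slope),
            "equilibrium_residual": eq_star.residual_norm,
        },
        equilibrium=eq_star,
    )


def build_pip(
    spec: SpecialismSpec,
    params: EcoParams,
    trait_axis: Sequence[float],
    neutral_band: float = NEUTRALITY_BAND,
) -> PipGrid:
    """Pairwise invasibility plot: sign of invasion fitness over a trait grid.

    For each resident value the endemic equilibrium is solved once
    (warm-started along the axis) and all mutants are scored against it.
    Residents without a stable endemic equilibrium are masked; if more than
    20% of the axis is masked the axis is considered ill-chosen and an error
    is raised.
    """
    axis = np.asarray(trait_axis, dtype=float)
    if axis.ndim != 1 or len(axis) < 2:
        raise ValueError("trait_axis must be a 1-D grid with at least two points")
    if np.any(axis <= 0) or np.any(np.diff(axis) <= 0):
        raise ValueError("trait_axis must be positive and strictly increasing")

    n = len(axis)
    signs = np.zeros((n, n), dtype=np.int8)
    ok = np.zeros(n, dtype=bool)
    eqs = _ResidentEquilibria(spec, params)
    for i, eps_res in enumerate(axis):
        eq = eqs(eps_res)
        if eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
            continue
        ok[i] = True
        for j, eps_mut in enumerate(axis):
            w = invasion_fitness(eps_mut, eq, spec, params).fitness_value
            if abs(w) < neutral_band:
                signs[i, j] = 0
            else:
                signs[i, j] = 1 if w > 0 else -1
    if np.count_nonzero(~ok) > 0.2 * n:
        raise ValueError(
            f"{np.count_nonzero(~ok)} of {n} resident values lack a stable endemic "
            "equilibrium; choose a different trait axis"
        )

    # diagonal sign-boundary candidates: flip of the local uphill direction
    singular: List[float] = []
    for i in range(n - 1):
        if not (ok[i] and ok[i + 1]):
            continue
        up_here = signs[i, i + 1] if i + 1 < n else 0
        up_next = signs[i + 1, i + 2] if i + 2 < n and ok[i + 1] else None
        if up_next is None:
            continue
        if up_here > 0 and up_next < 0:
            singular.append(float(0.5 * (axis[i] + axis[i + 2])))
    return PipGrid(axis, signs, ok, tuple(singular))
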
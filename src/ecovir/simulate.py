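"""Independent validation engines for the analytic adaptive-dynamics machinery.

Two oracles, deliberately built on the full nonlinear dynamics rather than
the linearized invasion condition:

* :func:`compete` integrates the six-compartment resident + mutant system
  from a rare-mutant introduction and classifies who wins — its outcome must
  agree with the sign of the analytic invasion fitness;
* :func:`trait_substitution_walk` plays the mutation-substitution game
  directly (a resident is replaced by any nearby mutant with positive
  invasion fitness) — its terminal trait must land on the singular strategy
  found by root solving.

A small timing diagnostic reports how fast a favourable mutant sweeps under
competitive, neutral and mutualistic host–host interactions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    EcoParams,
    ParasiteStrain,
    SpecialismCase,
    SpecialismSpec,
    SystemState,
    _rhs6,
    phenotype_from_trait,
)
from .equilibrium import EquilibriumClass, find_equilibrium
from .adaptive import NEUTRALITY_BAND, invasion_fitness

__all__ = [
    "Winner",
    "CompetitionOutcome",
    "TssTrajectory",
    "compete",
    "trait_substitution_walk",
    "invasion_timing_diagnostic",
]


class Winner(enum.Enum):
    RESIDENT = "resident"
    MUTANT = "mutant"
    COEXIST = "coexist"
    UNDECIDED = "undecided"


@dataclass(frozen=True)
class CompetitionOutcome:
    winner: Winner
    mutant_fraction: float
    final_state: SystemState
    horizon: float


@dataclass(frozen=True)
class TssTrajectory:
    epsilons: Tuple[float, ...]
    converged: bool

    @property
    def terminal(self) -> float:
        if not self.converged:
            raise ValueError("walk did not converge; no terminal trait")
        return self.epsilons[-1]


def _mutant_fraction(y: np.ndarray) -> float:
    tot = y[1] + y[3] + y[4] + y[5]
    return float((y[4] + y[5]) / tot) if tot > 0 else 0.0


def compete(
    resident_eps: float,
    mutant_eps: float,
    spec: SpecialismSpec,
    params: EcoParams,
    horizon: float = 4000.0,
    introduction: float = 1e-4,
    max_doublings: int = 3,
    win_fraction: float = 0.99,
    loss_fraction: float = 1e-6,
) -> CompetitionOutcome:
    """Integrate resident-vs-mutant competition from a rare introduction.

    The resident is placed at its stable endemic equilibrium and the mutant
    introduced at ``introduction`` times each resident infected density.
    Classification at the (doubling) horizon is by the mutant share of all
    infections: above ``win_fraction`` the mutant has swept, below
    ``loss_fraction`` it is lost.  A share that has stopped moving at an
    interior value is ``COEXIST``; still-moving shares are ``UNDECIDED``.
    """
    resident = phenotype_from_trait(resident_eps, spec, params)
    mutant = phenotype_from_trait(mutant_eps, spec, params)
    eq = find_equilibrium(resident, params)
    if eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
        raise ValueError(f"resident equilibrium is {eq.classification.value}")
    st = eq.state_hat
    y = np.array(
        [st.s1, st.i1, st.s2, st.i2, introduction * st.i1, introduction * st.i2]
    )

    def rhs(_t, yy):
        return _rhs6(yy, resident, mutant, params)

    def ev_win(_t, yy):
        return _mutant_fraction(yy) - win_fraction

    def ev_loss(_t, yy):
        return _mutant_fraction(yy) - loss_fraction

    ev_win.terminal = True
    ev_loss.terminal = True
    ev_loss.direction = -1.0

    t_used = 0.0
    span = horizon
    prev_frac = _mutant_fraction(y)
    for _ in range(max_doublings + 1):
        sol = solve_ivp(
            rhs,
            (0.0, span),
            y,
            method="LSODA",
            events=(ev_win, ev_loss),
            rtol=1e-9,
            atol=1e-12 * max(params.disease_free_density, 1.0),
        )
        y = np.clip(sol.y[:, -1], 0.0, None)
        t_used += float(sol.t[-1])
        frac = _mutant_fraction(y)
        if sol.status == 1:  # a terminal event fired
            winner = Winner.MUTANT if frac >= win_fraction * 0.999 else Winner.RESIDENT
            return CompetitionOutcome(winner, frac, SystemState.from_array(y), t_used)
        if frac >= win_fraction:
            return CompetitionOutcome(Winner.MUTANT, frac, SystemState.from_array(y), t_used)
        if frac <= loss_fraction:
            return CompetitionOutcome(Winner.RESIDENT, frac, SystemState.from_array(y), t_used)
        if abs(frac - prev_frac) < 1e-3 * max(frac, 1e-12):
            # interior share no longer moving
            winner = Winner.UNDECIDED if abs(frac - introduction) < introduction else Winner.COEXIST
            return CompetitionOutcome(winner, frac, SystemState.from_array(y), t_used)
        prev_frac = frac
        span *= 2.0
    return CompetitionOutcome(Winner.UNDECIDED, frac, SystemState.from_array(y), t_used)


def trait_substitution_walk(
    spec: SpecialismSpec,
    params: EcoParams,
    eps0: float,
    step: float = 0.01,
    max_events: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> TssTrajectory:
    """Sequential mutation-substitution walk along the fitness gradient.

    From resident trait ``eps0``, mutants at ``eps +/- step`` are scored by
    invasion fitness in the current resident's endemic equilibrium; a mutant
    with positive fitness replaces the resident.  The default deterministic
    variant takes the fitter neighbour; passing a seeded ``rng`` picks
    uniformly among the invading neighbours instead.  The walk halts (and is
    marked converged) when neither neighbour can invade.
    """
    eps = float(eps0)
    path: List[float] = [eps]
    warm: Optional[SystemState] = None
    for _ in range(max_events):
        strain = phenotype_from_trait(eps, spec, params)
        eq = find_equilibrium(strain, params, init=warm)
        if eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
            raise ValueError(
                f"walk left the endemic region at eps={eps:.6g} "
                f"({eq.classification.value})"
            )
        warm = eq.state_hat
        candidates = []
        for cand in (eps + step, eps - step):
            if cand <= 0:
                continue
            w = invasion_fitness(cand, eq, spec, params).fitness_value
            if w > NEUTRALITY_BAND:
                candidates.append((cand, w))
        if not candidates:
            return TssTrajectory(tuple(path), converged=True)
        if rng is None:
            eps = max(candidates, key=lambda cw: cw[1])[0]
        else:
            eps = candidates[int(rng.integers(len(candidates)))][0]
        path.append(eps)
    return TssTrajectory(tuple(path), converged=False)


def invasion_timing_diagnostic(
    spec: SpecialismSpec,
    params: EcoParams,
    pair: Tuple[float, float],
    r_magnitude: float = 2e-4,
    introduction: float = 1e-4,
    threshold: float = 0.5,
    max_time: float = 1e5,
) -> Dict[str, float]:
    """Time for a favourable mutant to reach half of all infections, by regime.

    Only meaningful for susceptibility specialism, where the *equilibrium*
    outcome is independent of the host–host interaction but the transient
    sweep speed is not.  Returns the crossing time under equal-magnitude
    competition, neutrality and mutualism.
    """
    if spec.case_id is not SpecialismCase.CASE1_SUSCEPTIBILITY:
        raise ValueError("timing diagnostic is defined for CASE1_SUSCEPTIBILITY")
    resident_eps, mutant_eps = pair
    out: Dict[str, float] = {}
    for label, r in (
        ("competition", -r_magnitude),
        ("neutral", 0.0),
        ("mutualism", +r_magnitude),
    ):
        p = params.with_interactions(r, r)
        resident = phenotype_from_trait(resident_eps, spec, p)
        mutant = phenotype_from_trait(mutant_eps, spec, p)
        eq = find_equilibrium(resident, p)
        if eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
            raise ValueError(f"no endemic resident equilibrium under {label}")
        w = invasion_fitness(mutant_eps, eq, spec, p).fitness_value
        if w <= NEUTRALITY_BAND:
            raise ValueError(
                f"pair {pair} is not invadable under {label} (fitness {w:.3e})"
            )
        st = eq.state_hat
        y0 = np.array(
            [st.s1, st.i1, st.s2, st.i2, introduction * st.i1, introduction * st.i2]
        )

        def ev(_t, yy):
            return _mutant_fraction(yy) - threshold

        ev.terminal = True
        ev.direction = 1.0
        sol = solve_ivp(
            lambda _t, yy: _rhs6(yy, resident, mutant, p),
            (0.0, max_time),
            y0,
            method="LSODA",
            events=(ev,),
            rtol=1e-9,
            atol=1e-12 * max(p.disease_free_density, 1.0),
        )
        if sol.status != 1:
            raise ValueError(f"mutant did not reach {threshold:.0%} within {max_time} under {label}")
        out[label] = float(sol.t_events[0][0])
    return out
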
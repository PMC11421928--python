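"""Community-interaction sweep experiments.

Three experimental designs probe how the ecological relationship between the
two hosts shapes ES virulence for each specialism mechanism and strength:

* **reciprocal, equal strength** — ``r12 = r21`` swept from strong competition
  to strong mutualism;
* **reciprocal, unequal strength** — the preferred host's effect on the
  non-preferred host is held fixed while the return effect is swept (separate
  mutualism and competition panels);
* **non-reciprocal** — ``r12 = -r21`` swept from "PH exploits NPH" through
  neutrality to "NPH exploits PH".

Results are tidy tables (one row per case x strength x interaction pair) with
a per-case relative ES virulence column scaled so each case's maximum row is
exactly 1.  Cells whose equilibrium or ESS computation fails are kept and
flagged, never dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_PARAMS,
    EcoParams,
    PreferredHost,
    SpecialismCase,
    SpecialismSpec,
)
from .adaptive import EssResult, find_ess

__all__ = [
    "SweepMode",
    "SweepDesign",
    "DEFAULT_STRENGTHS",
    "DEFAULT_R_MAX",
    "run_reciprocal_sweep",
    "run_asymmetric_sweep",
    "run_nonreciprocal_sweep",
    "specialism_strength_trends",
]

#: Four degrees of parasite specialism, weak to strong.
DEFAULT_STRENGTHS: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
#: Strongest interaction magnitude of the default sweeps.  At the default
#: parameterization endemic host densities are a few hundred, so
#: ``r * N ~ 0.07/time`` at the extremes — a few-percent perturbation of the
#: demographic rates.
DEFAULT_R_MAX = 3e-4
#: Held-fixed magnitude of the PH -> NPH effect in the asymmetric design.
DEFAULT_R_FIXED = 2e-4
#: Swept magnitude range of the NPH -> PH effect in the asymmetric design.
DEFAULT_R_ASYM_RANGE = (1e-4, 3e-4)

_FOUR_CASES = (
    SpecialismCase.CASE1_SUSCEPTIBILITY,
    SpecialismCase.CASE2_GROWTH,
    SpecialismCase.CASE3_TRANSMISSION,
    SpecialismCase.CASE4_TOLERANCE,
)


class SweepMode(enum.Enum):
    RECIPROCAL_EQUAL = "reciprocal_equal"
    RECIPROCAL_UNEQUAL = "reciprocal_unequal"
    NONRECIPROCAL = "nonreciprocal"


@dataclass(frozen=True)
class SweepDesign:
    """A sweep experiment: interaction grid x specialism specs."""

    mode: SweepMode
    r_grid: Tuple[Tuple[float, float], ...]
    cases: Tuple[SpecialismSpec, ...]
    fixed_r_value: Optional[float] = None

    def __post_init__(self) -> None:
        for r12, r21 in self.r_grid:
            if self.mode is SweepMode.RECIPROCAL_EQUAL and r12 != r21:
                raise ValueError("RECIPROCAL_EQUAL requires r12 == r21 for every pair")
            if self.mode is SweepMode.NONRECIPROCAL and r12 != -r21:
                raise ValueError("NONRECIPROCAL requires r12 == -r21 for every pair")


def default_specs(
    cases: Sequence[SpecialismCase] = _FOUR_CASES,
    strengths: Sequence[float] = DEFAULT_STRENGTHS,
    preferred_host: PreferredHost = PreferredHost.HOST1,
) -> Tuple[SpecialismSpec, ...]:
    """All (case, strength) combinations; the generalist appears once if listed."""
    specs: List[SpecialismSpec] = []
    for case in cases:
        if case is SpecialismCase.GENERALIST:
            specs.append(SpecialismSpec(case, 0.0, preferred_host))
        else:
            specs.extend(SpecialismSpec(case, s, preferred_host) for s in strengths)
    return tuple(specs)


def reciprocal_design(
    r_max: float = DEFAULT_R_MAX,
    n_r: int = 13,
    specs: Optional[Sequence[SpecialismSpec]] = None,
) -> SweepDesign:
    r_vals = np.linspace(-r_max, r_max, n_r)
    grid = tuple((float(r), float(r)) for r in r_vals)
    return SweepDesign(SweepMode.RECIPROCAL_EQUAL, grid, tuple(specs or default_specs()))


def nonreciprocal_design(
    r_max: float = DEFAULT_R_MAX,
    n_r: int = 13,
    specs: Optional[Sequence[SpecialismSpec]] = None,
) -> SweepDesign:
    # axis variable is the impact of the NPH on the PH (r12 with PH = host 1);
    # r12 > 0 means the PH benefits, i.e. the PH is the exploiter.
    r_vals = np.linspace(-r_max, r_max, n_r)
    grid = tuple((float(r), float(-r)) for r in r_vals)
    return SweepDesign(SweepMode.NONRECIPROCAL, grid, tuple(specs or default_specs()))


def asymmetric_design(
    sign: int,
    fixed_magnitude: float = DEFAULT_R_FIXED,
    swept_range: Tuple[float, float] = DEFAULT_R_ASYM_RANGE,
    n_r: int = 13,
    specs: Optional[Sequence[SpecialismSpec]] = None,
) -> SweepDesign:
    """One panel of the asymmetric-reciprocal design.

    ``sign=+1`` is the mutualism panel, ``sign=-1`` the competition panel.
    The PH -> NPH effect (``r21`` with PH = host 1) is held at
    ``sign * fixed_magnitude``; the NPH -> PH effect (``r12``) is swept in
    magnitude with the matching sign.
    """
    if sign not in (-1, +1):
        raise ValueError("sign must be +1 (mutualism) or -1 (competition)")
    mags = np.linspace(swept_range[0], swept_range[1], n_r)
    grid = tuple((float(sign * m), float(sign * fixed_magnitude)) for m in mags)
    return SweepDesign(
        SweepMode.RECIPROCAL_UNEQUAL,
        grid,
        tuple(specs or default_specs()),
        fixed_r_value=float(sign * fixed_magnitude),
    )


# --------------------------------------------------------------------------
# execution
# --------------------------------------------------------------------------

def _bracket_around(eps: float, width: float = 0.35) -> Tuple[float, float]:
    return (max(eps * (1 - width), 1e-3), eps * (1 + width))


def _ess_with_continuation(
    spec: SpecialismSpec,
    params: EcoParams,
    warm: Optional[EssResult],
    bracket: Tuple[float, float],
) -> EssResult:
    """Find the ESS, preferring a narrow bracket around a warm-start value."""
    if warm is not None:
        try:
            return find_ess(
                spec,
                params,
                bracket=_bracket_around(warm.epsilon_star),
                eq_init=warm.equilibrium.state_hat,
            )
        except ValueError:
            pass  # fall back to the full bracket
    return find_ess(spec, params, bracket=bracket)


def _sweep_order(grid: Sequence[Tuple[float, float]]) -> List[int]:
    """Indices ordered from the weakest interaction outward (continuation order)."""
    mags = [max(abs(a), abs(b)) for a, b in grid]
    start = int(np.argmin(mags))
    pos = list(range(start, len(grid)))
    neg = list(range(start - 1, -1, -1))
    return pos + neg


def _run_design(
    design: SweepDesign,
    params: EcoParams,
    bracket: Tuple[float, float],
    extra_cols: Optional[Dict[str, object]] = None,
) -> pd.DataFrame:
    rows = []
    order = _sweep_order(design.r_grid)
    for spec in design.cases:
        warm: Optional[EssResult] = None
        warm_by_index: Dict[int, EssResult] = {}
        for k, idx in enumerate(order):
            r12, r21 = design.r_grid[idx]
            p = params.with_interactions(r12, r21)
            # restart continuation when jumping back to the grid centre
            if k > 0 and abs(idx - order[k - 1]) != 1:
                warm = warm_by_index.get(order[0])
            row = {
                "case_id": spec.case_id.value,
                "strength": spec.strength,
                "preferred_host": spec.preferred_host.value,
                "r12": r12,
                "r21": r21,
            }
            try:
                ess = _ess_with_continuation(spec, p, warm, bracket)
                warm = ess
                warm_by_index[idx] = ess
                row.update(
                    epsilon_star=ess.epsilon_star,
                    alpha1=ess.alpha_realized[0],
                    alpha2=ess.alpha_realized[1],
                    max_es_virulence=ess.max_es_virulence,
                    classification=ess.classification.value,
                    n1_hat=ess.equilibrium.state_hat.n1,
                    n2_hat=ess.equilibrium.state_hat.n2,
                )
            except ValueError as exc:  # flagged, never dropped
                row.update(
                    epsilon_star=np.nan,
                    alpha1=np.nan,
                    alpha2=np.nan,
                    max_es_virulence=np.nan,
                    classification=f"failed: {exc}",
                    n1_hat=np.nan,
                    n2_hat=np.nan,
                )
            if extra_cols:
                row.update(extra_cols)
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["case_id", "strength", "r12", "r21"], ignore_index=True
    )
    # relative scaling: each specialism case's maximum row is exactly 1
    df["relative_es_virulence"] = df.groupby("case_id")["max_es_virulence"].transform(
        lambda v: v / v.max()
    )
    return df


def run_reciprocal_sweep(
    design: Optional[SweepDesign] = None,
    params: EcoParams = DEFAULT_PARAMS,
    bracket: Tuple[float, float] = (0.2, 6.0),
) -> pd.DataFrame:
    """ES virulence across equal-strength reciprocal interactions (competition to mutualism)."""
    design = design or reciprocal_design()
    if design.mode is not SweepMode.RECIPROCAL_EQUAL:
        raise ValueError("run_reciprocal_sweep requires a RECIPROCAL_EQUAL design")
    return _run_design(design, params, bracket)


def run_nonreciprocal_sweep(
    design: Optional[SweepDesign] = None,
    params: EcoParams = DEFAULT_PARAMS,
    bracket: Tuple[float, float] = (0.2, 6.0),
) -> pd.DataFrame:
    """ES virulence across exploiter/exploitee interactions (``r12 = -r21``)."""
    design = design or nonreciprocal_design()
    if design.mode is not SweepMode.NONRECIPROCAL:
        raise ValueError("run_nonreciprocal_sweep requires a NONRECIPROCAL design")
    df = _run_design(design, params, bracket)

    def _exploiter(row) -> str:
        ph = int(row["preferred_host"])
        r_to_ph = row["r12"] if ph == 1 else row["r21"]
        if r_to_ph > 0:
            return "PH"
        if r_to_ph < 0:
            return "NPH"
        return "none"

    df["exploiter"] = df.apply(_exploiter, axis=1)
    return df


def run_asymmetric_sweep(
    designs: Optional[Sequence[SweepDesign]] = None,
    params: EcoParams = DEFAULT_PARAMS,
    bracket: Tuple[float, float] = (0.2, 6.0),
) -> pd.DataFrame:
    """ES virulence for reciprocal but unequal interactions (both panels).

    By default runs the mutualism (+/+) and competition (-/-) panels with the
    PH -> NPH effect fixed and the NPH -> PH effect swept in magnitude.  Each
    row is annotated with the NPH's relative role: a more generous mutualist /
    stronger competitor when its effect on the PH outweighs the fixed return
    effect.
    """
    if designs is None:
        designs = (asymmetric_design(+1), asymmetric_design(-1))
    frames = []
    for design in designs:
        if design.mode is not SweepMode.RECIPROCAL_UNEQUAL:
            raise ValueError("run_asymmetric_sweep requires RECIPROCAL_UNEQUAL designs")
        sign = int(np.sign(design.r_grid[0][0]))
        panel = "mutualism" if sign > 0 else "competition"
        df = _run_design(design, params, bracket, extra_cols={"panel": panel})
        fixed = abs(design.fixed_r_value or design.r_grid[0][1])

        def _role(row) -> str:
            swept = abs(row["r12"])
            if swept > fixed:
                return "NPH more generous mutualist" if sign > 0 else "NPH stronger competitor"
            if swept < fixed:
                return "NPH less generous mutualist" if sign > 0 else "NPH weaker competitor"
            return "balanced"

        df["nph_role"] = df.apply(_role, axis=1)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    # rescale relative virulence jointly across panels within each case
    out["relative_es_virulence"] = out.groupby("case_id")["max_es_virulence"].transform(
        lambda v: v / v.max()
    )
    return out


def specialism_strength_trends(
    results: pd.DataFrame, rel_tol: float = 1e-5
) -> pd.DataFrame:
    """Monotonicity of max ES virulence in specialism strength, per (case, interaction).

    Requires at least two strengths per (case, r12, r21) group.  Verdicts:
    ``increasing``, ``decreasing``, ``flat`` (relative spread below
    ``rel_tol``) or ``non-monotone``.
    """
    needed = {"case_id", "strength", "r12", "r21", "max_es_virulence"}
    if not needed.issubset(results.columns):
        raise ValueError(f"results table must contain columns {sorted(needed)}")
    rows = []
    for (case_id, r12, r21), grp in results.groupby(["case_id", "r12", "r21"]):
        grp = grp.sort_values("strength")
        if len(grp) < 2:
            raise ValueError(
                f"need >= 2 strengths per (case, r) cell, got {len(grp)} for "
                f"({case_id}, {r12}, {r21})"
            )
        v = grp["max_es_virulence"].to_numpy()
        if np.any(np.isnan(v)):
            verdict = "failed"
        elif (v.max() - v.min()) <= rel_tol * abs(v).max():
            verdict = "flat"
        elif np.all(np.diff(v) > 0):
            verdict = "increasing"
        elif np.all(np.diff(v) < 0):
            verdict = "decreasing"
        else:
            verdict = "non-monotone"
        rows.append(
            {
                "case_id": case_id,
                "r12": r12,
                "r21": r21,
                "n_strengths": len(grp),
                "verdict": verdict,
                "spread": float(v.max() - v.min()) if not np.any(np.isnan(v)) else np.nan,
            }
        )
    return pd.DataFrame(rows)
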
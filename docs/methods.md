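# Methods

## Model and assumptions

`ecovir` implements a deterministic two-host, one-parasite SIS system with
host–host interactions entering through the birth term (`r_ij N_j S_i`):
only susceptible hosts reproduce, but all hosts of the partner type —
susceptible, resident-infected and (when present) mutant-infected — count
towards `N_j` and therefore towards both crowding and the interaction terms.
Co-infection is excluded: a host carries the resident strain or the mutant
strain, never both.  Inter- and intra-host contact rates are set equal, so
any contact-rate asymmetry is absorbed into the host susceptibility factors
`βS_i` and not exposed as a separate parameter.

Evolution is modelled by adaptive dynamics: rare mutants with small trait
deviations arise in a monomorphic resident population sitting at its stable
endemic equilibrium, and the trait substitutes along the local fitness
gradient.  The invasion criterion is the sign of
`Γ2M a11 + Γ1M a22 − Γ1M Γ2M` with `a_ii = βS_iM βT_iM Ŝ_i`; this is exactly
the condition for the 2×2 mutant-infected linearization (whose off-diagonal
structure is rank-one, `a_ij = βS_iM βT_jM Ŝ_i`) to have a positive dominant
eigenvalue.  It is evaluated at the resident's susceptible densities only,
and is exactly zero for the resident itself — a property the test suite
checks at machine precision.

## Trait, trade-offs and specialism mechanisms

The evolving scalar is the intra-host growth rate ε, with virulence
`α = f(ε)` (identity by default; `f` is injectable through
`phenotype_from_trait(..., virulence_fn=...)`) and saturating transmission
`βT = c ε^η`, `0 < η < 1`.  For a generalist this yields the classic
single-host optimum: maximizing `βT(ε)/(d+γ+α(ε))` gives
`ε* = η(d+γ)/(1−η)`, which the package's root-solved ESS reproduces and —
as the analytic structure demands — is entirely independent of `r12`, `r21`.

Specialism multiplies the baseline phenotype asymmetrically between the
preferred host (PH) and non-preferred host (NPH) with a single dimensionless
strength `s`:

* **case 1 (susceptibility)** `βS = 1 ± s`.  The invasion condition then
  factors into a host-density-free ratio test
  `βT(ε_M)/(d+γ+ε_M) > βT(ε)/(d+γ+ε)`, so ES virulence cannot depend on the
  host–host interaction *or* on `s`.  This exact invariance is a test oracle.
* **case 2 (growth)** realized growth is ε on the PH and `(1−s)ε` on the
  NPH, with virulence and transmission following each host's realized rate.
  By construction PH virulence exceeds NPH virulence by `1/(1−s)` at any
  trait value.
* **case 3 (transmission)** equal growth and virulence on both hosts;
  `βT,PH = (1+s) c ε^η` and `βT,NPH = (1−s) c ε^{η(1−s)}`.  The NPH curve is
  both *lower* and *flatter* (it saturates earlier in ε).  The shape change
  is essential, not cosmetic: if specialism only rescaled a common ε-shape,
  the weighted sum `(1+s)Ŝ1 + (1−s)Ŝ2` would be fixed by the resident and
  cancel from the singular-strategy condition, forcing the same total
  invariance as case 1.  A transmission specialist whose NPH converts extra
  parasite growth into propagules less efficiently makes the PH's
  transmission curve favour a higher growth optimum than the NPH's, which is
  what lets host frequencies steer the ESS.
* **case 4 (tolerance)** equal growth and transmission; virulence `(1−s)α`
  on the (tolerant) PH and `(1+s)α` on the NPH.

At `s = 0` all four mappings collapse to the generalist, continuously.

## Default parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `b` | susceptible birth rate | 4.0 | 1/time |
| `d` | natural death rate | 1.0 | 1/time |
| `q` | crowding coefficient | 1e−3 | 1/density |
| `gamma_rec` | recovery rate | 0.5 | 1/time |
| `c` | transmission trade-off scale | 0.01 | — |
| `eta` | transmission trade-off exponent | 0.5 | — |
| `r12`, `r21` | host–host interaction | 0 (swept to ±3e−4) | 1/(density·time) |

These give a disease-free carrying density `(b−d)/(bq) = 750` per host and
endemic densities of order 100–250, so the swept interaction magnitudes
`|r| ≤ 3e−4` perturb the demographic rates by up to a few percent
(`r·N ≈ 0.07` against rates of order one) — strong enough for clear
directional responses, weak enough never to destabilize coexistence.  The
trade-off scale `c` is the lever that sets this density scale (the
generalist optimum `ε* = 1.5` does not depend on it);
`scripts/tune_defaults.py` re-certifies any alternative parameter set over
the full default sweep range.  The default specialism strengths are
`{0.1, 0.2, 0.3, 0.4}` and interaction grids use 13 points (odd, so
neutrality `r = 0` is always included).

## Numerical strategy

**Equilibria.**  Candidate fixed points are polished with a Newton-type root
solve (`scipy.optimize.root`, hybr) using the exact analytic 4×4 Jacobian;
cold starts that land on a repeller fall back to stiff integration (LSODA,
rtol 1e−10) in windows with a stall detector (a RHS norm that stops
decreasing while still large flags an oscillatory attractor as
`NOT_CONVERGED` rather than returning a false fixed point).  Certified
`STABLE_ENDEMIC` equilibria must have max-abs RHS residual < 1e−9, negative
spectral abscissa, and both infected densities above the extinction
threshold (1e−8 of the disease-free density); tiny negative excursions below
1e−12 of that density are clipped to zero.  Warm-started continuation (from
the neighbouring sweep cell, ordered outward from `r = 0`) keeps sweeps on
one equilibrium branch and makes each solve essentially one Newton step.

**Selection gradient and ESS.**  The gradient is a central finite difference
of invasion fitness in the mutant trait (step `1e−4 · max(ε, 1)`; halving
the step is verified to change the estimate at second order).  The singular
point is a Brent root of the gradient (relative tolerance 1e−9 — tighter
than strictly needed, so that per-mil-scale trends across interaction grids
are resolved far above solver noise).  Classification uses the sign of the
mutant-fitness curvature (evolutionary stability) and of the gradient slope
in the resident trait (convergence stability); branching points would be
reported as such, never coerced to a CSS.

**PIPs.**  One equilibrium per resident grid value, all mutants scored
against it; |fitness| < 1e−10 is classified as neutral (the band that also
keeps the diagonal exactly neutral), and residents lacking a stable endemic
equilibrium are masked — more than 20% masked aborts with advice to choose a
different axis.

**Nonlinear oracles.**  `compete` integrates the six-compartment system from
a mutant introduced at 1e−4 of the resident infected densities and
classifies by the mutant share of all infections (≥0.99 sweep, ≤1e−6 loss),
with terminal events and horizon doubling (base 4000, up to 8×).  Pairs
inside a |fitness| band of 1e−3 are excluded from sign-agreement tests: the
deterministic sorting time diverges as neutrality is approached.
`trait_substitution_walk` is by default a deterministic hill-climb (the
fitter invading neighbour replaces the resident), so oracle tests are
seed-free; a stochastic variant picks uniformly among invading neighbours
from an explicit seeded generator.

## What the sweeps show at the defaults

All directional results are computed, not asserted: the generalist and the
susceptibility specialist are interaction-invariant (exactly, per the
reductions above); growth and tolerance specialists evolve strictly less
virulence as equal reciprocal interactions slide from competition to
mutualism (drops of ≈0.1% and ≈0.3% across the default range, growing with
`s`); under exploitation the transmission and tolerance specialists peak
when the PH is the exploiter and the growth specialist when the PH is the
exploitee, with the growth case's non-reciprocal extremes bracketing its
reciprocal values; stronger specialism raises ES virulence for growth and
tolerance specialists, lowers it for transmission specialists, and leaves
the susceptibility specialist untouched.  The mechanism is host-frequency
feedback: the per-host fitness ratios `βT_i/(d+γ+α_i)` peak at different
trait values for PH and NPH, and the interaction structure re-weights them
through `Ŝ1, Ŝ2`.

## Limitations

* Two hosts, one parasite; no co-infection, no host evolution or
  coevolution of specialism, no spatial or age structure.
* Infected hosts do not reproduce; host–host interactions act on the birth
  rate of susceptibles only (infected partners still contribute to `N_j`).
  Chronic-infection systems where infected hosts reproduce are out of scope.
* Exploitative interactions are phenomenological (+/− birth-rate effects),
  not mechanistic predation (no handling time or biomass conversion).
* The analysis assumes a stable endemic point equilibrium; parameter
  regions with oscillatory attractors are refused (`NOT_CONVERGED`), not
  analysed.
* The specialism mappings are one defensible parameterization of
  qualitative mechanisms ("more susceptible", "transmits better", …); the
  *directions* of the reported trends are the robust content, not absolute
  virulence magnitudes, which is why sweep tables carry the per-case
  relative scaling.
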
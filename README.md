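# ecovir

Eco-evolutionary modelling of virulence for a parasite shared by **two
ecologically interacting hosts**.

Most virulence-evolution theory treats a single host–parasite pair in
isolation, yet multi-host parasites are the norm and their hosts typically
have their own ecological relationships — competing for resources, trading
mutualistic benefits, or exploiting one another. `ecovir` asks how that
*community context* feeds back on parasite evolution: for which mechanisms of
parasite specialism does the host–host interaction shift the evolutionarily
stable (ES) virulence, and in which direction?

It is intended for theoretical ecologists and evolutionary epidemiologists
who want a tested, scriptable implementation of the two-host SIS
adaptive-dynamics framework: equilibrium analysis, invasion fitness, pairwise
invasibility plots (PIPs), ES-virulence computation and community-interaction
sweeps, plus independent nonlinear-dynamics validators.

## The model

Susceptible and infected hosts of types *i* = 1, 2 share one parasite
(SIS dynamics; recovered hosts return to the susceptible pool):

```
dS1/dt = b(1 − qN1)S1 − dS1 + r12 N2 S1 − βS1βT1 S1 I1 − βS1βT2 S1 I2 + γI1
dI1/dt = βS1βT1 S1 I1 + βS1βT2 S1 I2 − γI1 − (d + α1) I1
```

(and symmetrically for host 2 with `r21 N1 S2`).  Only susceptible hosts
reproduce; the signed coefficients `r12`, `r21` let the partner host raise or
depress the birth rate — matching signs give mutualism (+/+) or competition
(−/−), opposite signs exploitation.  Transmission is split into a host
susceptibility factor `βS_i` and a parasite onward-transmission factor
`βT_j`, so the force of infection on host *i* is `βS_i (βT1 I1 + βT2 I2)`.

The evolving trait is the intra-host parasite growth rate ε, tied to the
life-history trade-offs `α_i = ε_i` (virulence) and `βT_i = c ε_i^η` with
`η < 1` (saturating transmission).  Because the conventional symbol γ is used
both for recovery and for the trade-off exponent in this literature, the
package names them `gamma_rec` and `eta`.

Four mechanisms of specialism distinguish a preferred host (PH) from a
non-preferred host (NPH), each controlled by a strength `s ∈ [0, 1)`:

| case | mechanism | PH vs NPH |
|------|-----------|-----------|
| 1 | susceptibility | `βS = 1 ± s` |
| 2 | intra-host growth | realized growth `ε` vs `(1−s)ε` |
| 3 | onward transmission | elevated `βT` curve vs lowered, earlier-saturating curve |
| 4 | tolerance | virulence `(1−s)α` vs `(1+s)α` |

A rare mutant with trait ε_M invades the resident's endemic equilibrium
`(Ŝ1, Î1, Ŝ2, Î2)` exactly when

```
Γ2M βS1M βT1M Ŝ1 + Γ1M βS2M βT2M Ŝ2 − Γ1M Γ2M > 0,   Γ_iM = d + γ + α_iM,
```

the dominant-eigenvalue condition of the mutant-infected linearization.
Singular strategies are roots of the selection gradient, classified for
evolutionary and convergence stability (CSS etc.).  ES *virulence* reported
on sweep axes is the larger of the two realized virulences.

## Worked example

ES virulence for a growth-rate specialist (case 2, `s = 0.3`) when its two
hosts are strong competitors:

```python
from ecovir import *
from ecovir.model import DEFAULT_PARAMS

params = DEFAULT_PARAMS.with_interactions(-3e-4, -3e-4)   # strong competition
spec = SpecialismSpec(SpecialismCase.CASE2_GROWTH, strength=0.3)
result = find_ess(spec, params)
print(result.summary())
```

```
singular trait epsilon* : 1.7941253
realized alpha (host 1) : 1.7941253
realized alpha (host 2) : 1.2558877
max ES virulence        : 1.7941253
classification          : css
selection gradient      : -4.950e-12
fitness curvature       : -6.939e-01
gradient slope          : -6.938e-01
```

The singular growth rate 1.794 exceeds the generalist optimum
`η(d+γ)/(1−η) = 1.5`; the preferred host carries the full virulence, the
non-preferred host the fraction `(1−s)` of it, and the negative curvature
and gradient slope certify a continuously stable strategy.  Repeating under
strong mutualism (`r12 = r21 = +3e-4`) gives a lower value — competition
between hosts selects for a more virulent shared parasite:

```
competition : max ES virulence = 1.7941
mutualism   : max ES virulence = 1.7921
```

The same analyses are available from the shell:

```
ecovir ess   --case case2 --strength 0.3 --r=-3e-4 --out runs/ess
ecovir sweep --mode reciprocal --out runs/sweep --plot
ecovir pip   --case generalist --out runs/pip --plot
ecovir validate --case case2 --strength 0.3 --pairs 50 --out runs/val
```

Every run writes CSV output plus a JSON sidecar with the exact resolved
configuration; identical configurations produce byte-identical CSVs.

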
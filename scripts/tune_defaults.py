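#!/usr/bin/env python
"""Diagnostic for the default parameterization.

Verifies that the shipped defaults admit a stable endemic coexistence
equilibrium, and an ES-virulence bracket with a sign change, across the full
default interaction range for every specialism case and strength.  Run this
after changing any default in ``ecovir.model.EcoParams`` (or to vet an
alternative parameter set passed as a YAML/JSON config):

    python scripts/tune_defaults.py [--config my_params.yaml]

Exits non-zero, listing the failing cells, if any combination lacks a
certified equilibrium or a usable ESS bracket.
"""

from __future__ import annotations

import argparse
import sys

import numpy as np

from ecovir.adaptive import find_ess
from ecovir.config import load_config
from ecovir.equilibrium import EquilibriumClass, find_equilibrium
from ecovir.model import DEFAULT_PARAMS, SpecialismCase, SpecialismSpec, phenotype_from_trait
from ecovir.sweeps import DEFAULT_R_MAX, DEFAULT_STRENGTHS

CASES = (
    SpecialismCase.GENERALIST,
    SpecialismCase.CASE1_SUSCEPTIBILITY,
    SpecialismCase.CASE2_GROWTH,
    SpecialismCase.CASE3_TRANSMISSION,
    SpecialismCase.CASE4_TOLERANCE,
)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", help="optional config file with a params block")
    ap.add_argument("--n-r", type=int, default=7, help="interaction grid points")
    args = ap.parse_args()
    params = load_config(args.config).params if args.config else DEFAULT_PARAMS

    failures = []
    n_cells = 0
    for case in CASES:
        strengths = (0.0,) if case is SpecialismCase.GENERALIST else DEFAULT_STRENGTHS
        for s in strengths:
            spec = SpecialismSpec(case, s)
            for r in np.linspace(-DEFAULT_R_MAX, DEFAULT_R_MAX, args.n_r):
                for r12, r21 in ((r, r), (r, -r)):
                    n_cells += 1
                    p = params.with_interactions(float(r12), float(r21))
                    eq = find_equilibrium(phenotype_from_trait(1.5, spec, p), p)
                    if eq.classification is not EquilibriumClass.STABLE_ENDEMIC:
                        failures.append(
                            f"equilibrium {case.value} s={s} r=({r12:+.1e},{r21:+.1e}): "
                            f"{eq.classification.value}"
                        )
                        continue
                    try:
                        find_ess(spec, p)
                    except ValueError as exc:
                        failures.append(
                            f"ess {case.value} s={s} r=({r12:+.1e},{r21:+.1e}): {exc}"
                        )
    if failures:
        print(f"{len(failures)}/{n_cells} cells FAILED:")
        for f in failures:
            print(" ", f)
        return 1
    print(f"all {n_cells} cells admit a stable endemic equilibrium and an ESS")
    return 0


if __name__ == "__main__":
    sys.exit(main())
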
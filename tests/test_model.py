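"""Unit and property tests for the core model layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecovir.model import (
    EcoParams,
    ParasiteStrain,
    PreferredHost,
    SpecialismCase,
    SpecialismSpec,
    SystemState,
    phenotype_from_trait,
    resident_mutant_rhs,
    resident_rhs,
)

from conftest import ALL_CASES, FOUR_CASES, spec_for


class TestValidation:
    def test_params_reject_bad_rates(self):
        with pytest.raises(ValueError):
            EcoParams(b=1.0, d=2.0)  # death exceeds birth
        with pytest.raises(ValueError):
            EcoParams(q=0.0)
        with pytest.raises(ValueError):
            EcoParams(eta=1.0)
        with pytest.raises(ValueError):
            EcoParams(c=-1.0)

    def test_specialism_strength_domain(self):
        with pytest.raises(ValueError):
            SpecialismSpec(SpecialismCase.CASE2_GROWTH, 1.0)
        with pytest.raises(ValueError):
            SpecialismSpec(SpecialismCase.CASE2_GROWTH, -0.1)
        with pytest.raises(ValueError):
            SpecialismSpec(SpecialismCase.GENERALIST, 0.2)

    def test_phenotype_rejects_nonpositive_trait(self, params, generalist):
        with pytest.raises(ValueError):
            phenotype_from_trait(0.0, generalist, params)
        with pytest.raises(ValueError):
            phenotype_from_trait(-1.0, generalist, params)

    def test_state_rejects_negative_compartments(self):
        with pytest.raises(ValueError):
            SystemState(1.0, -0.1, 1.0, 0.1)


class TestPhenotypeMapping:
    def test_generalist_is_symmetric(self, params, generalist):
        eps = 1.7
        ph = phenotype_from_trait(eps, generalist, params)
        assert ph.beta_s[0] == ph.beta_s[1]
        assert ph.beta_t[0] == ph.beta_t[1] == params.c * eps**params.eta
        assert ph.alpha[0] == ph.alpha[1] == eps

    @pytest.mark.parametrize("case", FOUR_CASES)
    def test_zero_strength_specialism_is_generalism(self, params, generalist, case):
        eps = 1.3
        base = phenotype_from_trait(eps, generalist, params)
        zero = phenotype_from_trait(eps, SpecialismSpec(case, 0.0), params)
        assert zero.beta_s == base.beta_s
        assert zero.beta_t == base.beta_t
        assert zero.alpha == base.alpha

    def test_growth_case_transmission_ratio(self, params):
        # hand derivation: betaT_i = c * eps_i**eta with eps_2 = (1-s) eps,
        # so betaT1/betaT2 = (1/(1-s))**eta and alpha follows realized growth
        eps, s = 1.8, 0.25
        ph = phenotype_from_trait(eps, spec_for(SpecialismCase.CASE2_GROWTH, s), params)
        assert ph.alpha == (eps, (1 - s) * eps)
        assert ph.beta_t[0] / ph.beta_t[1] == pytest.approx(
            (1.0 / (1 - s)) ** params.eta, rel=1e-12
        )

    def test_susceptibility_case_touches_only_beta_s(self, params):
        eps, s = 1.2, 0.4
        ph = phenotype_from_trait(eps, spec_for(SpecialismCase.CASE1_SUSCEPTIBILITY, s), params)
        assert ph.beta_s == (1 + s, 1 - s)
        assert ph.alpha[0] == ph.alpha[1] == eps
        assert ph.beta_t[0] == ph.beta_t[1]

    def test_tolerance_case_touches_only_alpha(self, params):
        eps, s = 1.2, 0.4
        ph = phenotype_from_trait(eps, spec_for(SpecialismCase.CASE4_TOLERANCE, s), params)
        assert ph.alpha == ((1 - s) * eps, (1 + s) * eps)
        assert ph.beta_t[0] == ph.beta_t[1]
        assert ph.beta_s == (1.0, 1.0)

    def test_transmission_case_orders_hosts(self, params):
        # the preferred host transmits more for any trait value in range
        s = 0.4
        spec = spec_for(SpecialismCase.CASE3_TRANSMISSION, s)
        for eps in (0.3, 0.8, 1.5, 3.0):
            ph = phenotype_from_trait(eps, spec, params)
            assert ph.beta_t[0] > ph.beta_t[1]
            assert ph.alpha[0] == ph.alpha[1] == eps

    @pytest.mark.parametrize("case", ALL_CASES)
    @given(eps=st.floats(0.05, 8.0), s=st.floats(0.0, 0.8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_transmission_monotone_virulence_nondecreasing(self, case, eps, s):
        params = EcoParams()
        spec = SpecialismSpec(case, 0.0 if case is SpecialismCase.GENERALIST else s)
        lo = phenotype_from_trait(eps, spec, params)
        hi = phenotype_from_trait(eps * 1.05, spec, params)
        assert hi.beta_t[0] > lo.beta_t[0]
        assert hi.beta_t[1] > lo.beta_t[1]
        assert hi.alpha[0] >= lo.alpha[0]
        assert hi.alpha[1] >= lo.alpha[1]

    @pytest.mark.parametrize("case", FOUR_CASES)
    def test_mapping_continuous_at_zero_strength(self, params, case):
        eps = 1.4
        base = phenotype_from_trait(eps, SpecialismSpec(case, 0.0), params)
        near = phenotype_from_trait(eps, SpecialismSpec(case, 1e-9), params)
        for a, b in zip(
            base.beta_s + base.beta_t + base.alpha,
            near.beta_s + near.beta_t + near.alpha,
        ):
            assert a == pytest.approx(b, abs=1e-7)


def _hand_rhs(state, strain, p):
    """Independent arithmetic oracle: each flux term written out explicitly."""
    s1, i1, s2, i2 = state.s1, state.i1, state.s2, state.i2
    n1, n2 = s1 + i1, s2 + i2
    bs1, bs2 = strain.beta_s
    bt1, bt2 = strain.beta_t
    a1, a2 = strain.alpha
    ds1 = (
        p.b * (1 - p.q * n1) * s1
        - p.d * s1
        + p.r12 * n2 * s1
        - bs1 * bt1 * s1 * i1
        - bs1 * bt2 * s1 * i2
        + p.gamma_rec * i1
    )
    di1 = bs1 * bt1 * s1 * i1 + bs1 * bt2 * s1 * i2 - p.gamma_rec * i1 - (p.d + a1) * i1
    ds2 = (
        p.b * (1 - p.q * n2) * s2
        - p.d * s2
        + p.r21 * n1 * s2
        - bs2 * bt2 * s2 * i2
        - bs2 * bt1 * s2 * i1
        + p.gamma_rec * i2
    )
    di2 = bs2 * bt2 * s2 * i2 + bs2 * bt1 * s2 * i1 - p.gamma_rec * i2 - (p.d + a2) * i2
    return ds1, di1, ds2, di2


class TestRhs:
    def test_extinction_is_fixed_point(self, params, generalist):
        strain = phenotype_from_trait(1.5, generalist, params)
        assert resident_rhs(SystemState(0, 0, 0, 0), strain, params) == (0, 0, 0, 0)

    def test_disease_free_density_is_fixed_point(self, params, generalist):
        # solve b(1 - q S) - d = 0 analytically: S = (b - d)/(b q)
        k = (params.b - params.d) / (params.b * params.q)
        strain = phenotype_from_trait(1.5, generalist, params)
        out = resident_rhs(SystemState(k, 0, k, 0), strain, params)
        assert all(abs(v) < 1e-10 * k for v in out)

    def test_matches_term_by_term_oracle(self):
        p = EcoParams(r12=2e-4, r21=-1e-4)
        strain = phenotype_from_trait(
            1.3, spec_for(SpecialismCase.CASE2_GROWTH, 0.3), p
        )
        state = SystemState(1.0, 0.1, 2.0, 0.2)
        got = resident_rhs(state, strain, p)
        want = _hand_rhs(state, strain, p)
        assert got == pytest.approx(want, rel=1e-14)

    @given(
        s1=st.floats(0, 500),
        i1=st.floats(0, 500),
        s2=st.floats(0, 500),
        i2=st.floats(0, 500),
        eps=st.floats(0.2, 4.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_host_counts_conserved_by_infection_and_recovery(self, s1, i1, s2, i2, eps):
        # dN_i must consist of birth, death, interaction and virulence only:
        # infection and recovery move hosts within a type, never across N_i
        p = EcoParams(r12=-2e-4, r21=1e-4)
        strain = phenotype_from_trait(eps, spec_for(SpecialismCase.CASE4_TOLERANCE, 0.2), p)
        st4 = SystemState(s1, i1, s2, i2)
        ds1, di1, ds2, di2 = resident_rhs(st4, strain, p)
        n1, n2 = s1 + i1, s2 + i2
        dn1_expect = p.b * (1 - p.q * n1) * s1 - p.d * n1 + p.r12 * n2 * s1 - strain.alpha[0] * i1
        dn2_expect = p.b * (1 - p.q * n2) * s2 - p.d * n2 + p.r21 * n1 * s2 - strain.alpha[1] * i2
        scale = max(1.0, abs(dn1_expect), abs(dn2_expect))
        assert ds1 + di1 == pytest.approx(dn1_expect, abs=1e-9 * scale)
        assert ds2 + di2 == pytest.approx(dn2_expect, abs=1e-9 * scale)

    @given(
        s1=st.floats(0.1, 300),
        i1=st.floats(0.1, 300),
        s2=st.floats(0.1, 300),
        i2=st.floats(0.1, 300),
        eps=st.floats(0.3, 3.0),
        s=st.floats(0.0, 0.6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_host_swap_symmetry(self, s1, i1, s2, i2, eps, s):
        # swapping preferred host together with host labels and r12<->r21
        # relabels the dynamics exactly
        p = EcoParams(r12=2e-4, r21=-1.5e-4)
        p_swapped = EcoParams(r12=p.r21, r21=p.r12)
        for case in FOUR_CASES:
            spec = SpecialismSpec(case, s, PreferredHost.HOST1)
            a = resident_rhs(
                SystemState(s1, i1, s2, i2), phenotype_from_trait(eps, spec, p), p
            )
            b = resident_rhs(
                SystemState(s2, i2, s1, i1),
                phenotype_from_trait(eps, spec.swapped(), p_swapped),
                p_swapped,
            )
            assert a[0] == pytest.approx(b[2], rel=1e-12, abs=1e-12)
            assert a[1] == pytest.approx(b[3], rel=1e-12, abs=1e-12)
            assert a[2] == pytest.approx(b[0], rel=1e-12, abs=1e-12)
            assert a[3] == pytest.approx(b[1], rel=1e-12, abs=1e-12)


class TestMutantRhs:
    def test_mutant_free_reduces_to_resident(self, params):
        spec = spec_for(SpecialismCase.CASE3_TRANSMISSION, 0.2)
        res = phenotype_from_trait(1.4, spec, params)
        mut = phenotype_from_trait(1.6, spec, params)
        st6 = SystemState(3.0, 0.4, 2.0, 0.3, 0.0, 0.0)
        full = resident_mutant_rhs(st6, res, mut, params)
        part = resident_rhs(SystemState(3.0, 0.4, 2.0, 0.3), res, params)
        assert full[:4] == pytest.approx(part, rel=1e-14)
        assert full[4] == full[5] == 0.0

    def test_identical_strains_pool_like_relabeling(self, params, generalist):
        # splitting the infected class between two identical strains must
        # reproduce the pooled resident dynamics
        strain = phenotype_from_trait(1.5, generalist, params)
        s1, i1, s2, i2 = 100.0, 80.0, 90.0, 70.0
        f = 0.3
        full = resident_mutant_rhs(
            SystemState(s1, (1 - f) * i1, s2, (1 - f) * i2, f * i1, f * i2),
            strain,
            strain,
            params,
        )
        pooled = resident_rhs(SystemState(s1, i1, s2, i2), strain, params)
        assert full[0] == pytest.approx(pooled[0], rel=1e-12)
        assert full[2] == pytest.approx(pooled[2], rel=1e-12)
        assert full[1] + full[4] == pytest.approx(pooled[1], rel=1e-12)
        assert full[3] + full[5] == pytest.approx(pooled[3], rel=1e-12)

    def test_all_zero_state_is_fixed(self, params, generalist):
        strain = phenotype_from_trait(1.5, generalist, params)
        out = resident_mutant_rhs(SystemState(0, 0, 0, 0, 0, 0), strain, strain, params)
        assert out == (0,) * 6
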
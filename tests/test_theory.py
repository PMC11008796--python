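import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwasconf import theory
from gwasconf.ld import cis_ld, double_het_fractions, het_fraction, trans_ld

from conftest import random_phased_fixture


class TestPopulationExpectation:
    def test_reduces_to_truth_without_confounds(self):
        p = np.array([0.5, 0.3, 0.2])
        D = np.diag(p * (1 - p))
        Z = np.zeros((3, 3))
        ad = np.array([1.0, 2.0, 0.5])
        est = theory.expected_population_estimate(D, Z, Z, Z, ad, p=p, F=0.0)
        assert np.allclose(est, ad)

    def test_three_locus_hand_oracle(self):
        # scalar hand evaluation of the full expression at locus 0
        p = np.array([0.5, 0.4, 0.3])
        D = np.array([[0.25, 0.02, -0.01],
                      [0.02, 0.24, 0.005],
                      [-0.01, 0.005, 0.21]])
        Dt = np.array([[0.0, 0.01, 0.0],
                       [0.01, 0.0, -0.02],
                       [0.0, -0.02, 0.0]])
        Dp = 0.5 * D
        Dtp = 0.5 * Dt
        ad = np.array([1.0, 0.5, 2.0])
        ai = np.array([0.1, 0.0, 0.3])
        env = np.array([0.05, 0.0, 0.0])
        est = theory.expected_population_estimate(D, Dt, Dp, Dtp, ad, ai, p=p, F=0.0,
                                                  env_cov=env)
        V0 = 2 * 0.5 * 0.5
        direct = (0.25 * 1 + 0.02 * 0.5 + (-0.01) * 2) + (0.0 * 1 + 0.01 * 0.5 + 0.0 * 2)
        indirect = ((0.125 + 0.0 + 2 * 0.0) * 0.1
                    + (0.01 + 0.005 + 2 * 0.01) * 0.0
                    + (-0.005 + 0.0 + 2 * 0.0) * 0.3)
        hand = 2 / V0 * (direct + indirect + 0.5 * 0.05)
        assert est[0] == pytest.approx(hand, abs=1e-12)

    def test_stratification_plugin_matches_frequency_product(self):
        """Plugging the two-population LD into the population expectation
        reproduces the (p1-p2)(p1-p2) confound per locus."""
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0.3, 0.7, 4)
        p2 = rng.uniform(0.3, 0.7, 4)
        ad = rng.uniform(0.5, 1.5, 4)
        DS, DtS = theory.stratification_ld(p1, p2)
        pbar = (p1 + p2) / 2
        # mixture cis-LD = stratification LD (within-population LD zero);
        # diagonal of D must be the mixture haploid variance
        D = DS.copy()
        np.fill_diagonal(D, pbar * (1 - pbar))
        Dt = DtS.copy()
        F = DS.diagonal() / (pbar * (1 - pbar) + 1e-300)
        V = 2 * pbar * (1 - pbar) * (1 + F)
        est = theory.expected_population_estimate(D, Dt, D, Dt, ad, p=pbar, F=F)
        lam = 0
        confound = sum((p1[k] - p2[k]) * (p1[lam] - p2[lam]) * ad[k]
                       for k in range(4) if k != lam)
        expected0 = (2 * (D[lam, lam] + DS[lam, lam]) * ad[lam] + confound) / V[lam]
        assert est[0] == pytest.approx(expected0, abs=1e-12)


class TestFamilyExpectation:
    def test_zero_bias_when_cis_equals_trans(self):
        # equilibrium AM / two-population structure: D' == D~' off-diagonal,
        # so only the local (diagonal) term survives
        D = np.full((3, 3), 0.03)
        np.fill_diagonal(D, 0.25)
        Dt = np.full((3, 3), 0.03)
        np.fill_diagonal(Dt, 0.0)
        c = np.full((3, 3), 0.2)
        np.fill_diagonal(c, 0.0)
        ad = np.ones(3)
        H = np.full(3, 0.5)
        est = theory.expected_family_estimate(D, Dt, ad, H, c)
        local = (2 / 0.5) * 1.0 * (0.25 - 0.0) * 1.0
        assert np.allclose(est, local)

    def test_unlinked_confounders_cannot_bias(self):
        Dp = np.array([[0.25, 0.05], [0.05, 0.25]])
        Dtp = np.zeros((2, 2))
        c = np.array([[0.0, 0.5], [0.5, 0.0]])
        est = theory.expected_family_estimate(Dp, Dtp, np.array([0.0, 1.0]),
                                              np.full(2, 0.5), c)
        assert est[0] == 0.0  # (1 - 2c) kills the unlinked confounder

    def test_hand_value_single_linked_confounder(self):
        # c = 0.1, D' - D~' = 0.05, alpha = 1, H = 0.5:
        # (2/0.5) * 0.8 * 0.05 * 1 = 0.16
        Dp = np.array([[0.0, 0.05], [0.05, 0.0]])
        Dtp = np.zeros((2, 2))
        c = np.array([[0.0, 0.1], [0.1, 0.0]])
        est = theory.expected_family_estimate(Dp, Dtp, np.array([0.0, 1.0]),
                                              np.full(2, 0.5), c)
        assert est[0] == pytest.approx(0.16, abs=1e-12)

    def test_coupling_repulsion_form_identical_on_phased_fixtures(self, rng):
        """The (1-2c)(D'-D~') and (1/2-c)(Hcoup-Hrep) forms agree exactly."""
        for _ in range(10):
            haps = random_phased_fixture(rng, n=30, n_loci=5)
            Dp, Dtp = cis_ld(haps), trans_ld(haps)
            H = het_fraction(haps)
            if np.any(H == 0):
                continue
            coup, rep = double_het_fractions(haps)
            c = rng.uniform(0, 0.5, (5, 5))
            c = (c + c.T) / 2
            np.fill_diagonal(c, 0.0)
            ad = rng.normal(size=5) ** 2
            a, b = theory.expected_family_estimate(Dp, Dtp, ad, H, c,
                                                   coupling_rep=(coup, rep))
            assert np.allclose(a, b, atol=1e-12)


class TestUntransmittedExpectation:
    def _random_inputs(self, rng, L=4):
        A = rng.normal(0, 0.02, (L, L))
        Dp = (A + A.T) / 2
        B = rng.normal(0, 0.02, (L, L))
        Dtp = (B + B.T) / 2
        C = rng.normal(0, 0.02, (L, L))
        Dt = (C + C.T) / 2
        c = rng.uniform(0, 0.5, (L, L))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 0)
        ad = rng.uniform(0, 1, L)
        ai = rng.uniform(0, 0.5, L)
        H = rng.uniform(0.3, 0.6, L)
        return Dp, Dtp, Dt, c, ad, ai, H

    def test_no_ld_no_indirect_gives_zero(self):
        Z = np.zeros((3, 3))
        est = theory.expected_untransmitted_estimate(
            Z, Z, Z, np.ones(3), np.zeros(3), np.full(3, 0.5), np.full((3, 3), 0.25))
        assert np.allclose(est, 0.0)

    def test_local_indirect_effect_recovered_at_F_zero(self):
        # only the local parental-LD diagonal and alpha_i at the locus itself
        L = 2
        Dp = np.diag([0.25, 0.25])
        Z = np.zeros((L, L))
        c = np.array([[0.0, 0.5], [0.5, 0.0]])
        ai = np.array([0.7, 0.0])
        est = theory.expected_untransmitted_estimate(
            Dp, Z, Z, np.zeros(L), ai, np.full(L, 0.5), c)
        # 2/H * D'_ll * alpha_i = (2/0.5) * 0.25 * 0.7
        assert est[0] == pytest.approx((2 / 0.5) * 0.25 * 0.7)

    def test_general_F_form_reduces_to_F0_form(self, rng):
        """The general-F expression equals the F = 0 expression at F = 0."""
        for _ in range(10):
            Dp, Dtp, Dt, c, ad, ai, H = self._random_inputs(rng)
            full = theory.expected_untransmitted_estimate(
                Dp, Dtp, Dt, ad, ai, H, c, F=0.0)
            # independent F=0 oracle, written directly from the simple form
            simple = (2 * ((Dp * c + Dtp * (1 - c) + Dt) @ ad)
                      + 2 * ((Dp + Dtp + 2 * Dt) @ ai)) / H
            assert np.allclose(full, simple, atol=1e-12)

    def test_hand_value_at_nonzero_F(self, rng):
        Dp, Dtp, Dt, c, ad, ai, H = self._random_inputs(rng, L=2)
        F = 0.2
        est = theory.expected_untransmitted_estimate(Dp, Dtp, Dt, ad, ai, H, c, F=F)
        lam = 0
        s = 0.0
        for k in range(2):
            s += (Dp[lam, k] * ((1 + 3 * F) * c[lam, k] - 2 * F)
                  + Dtp[lam, k] * (-(1 + 3 * F) * c[lam, k] + 1 + F)
                  + (1 - F) * Dt[lam, k]) * ad[k]
        s2 = sum((Dp[lam, k] + Dtp[lam, k] + 2 * Dt[lam, k]) * ai[k] for k in range(2))
        hand = (2 * s + 2 * (1 - F) * s2) / (H[lam] * (1 + 3 * F))
        assert est[0] == pytest.approx(hand, abs=1e-12)


class TestAMClosedForms:
    def test_same_trait_inflation_height_parameters(self):
        assert theory.am_equilibrium_inflation(0.8, 0.25) == pytest.approx(1.25)

    def test_cross_trait_asymptotes(self):
        assert theory.am_equilibrium_inflation(1.0, 0.2, "cross_asym") == pytest.approx(0.1)
        assert theory.am_equilibrium_inflation(1.0, 0.2, "cross_sym") == pytest.approx(0.2)

    def test_no_am_means_no_inflation(self):
        assert theory.am_equilibrium_inflation(0.8, 0.0) == 1.0
        assert theory.am_equilibrium_inflation(0.8, 0.0, "cross_asym") == 0.0

    def test_divergent_regime_rejected(self):
        with pytest.raises(ValueError):
            theory.am_equilibrium_inflation(1.0, 1.0)

    def test_architecture_scaling(self):
        assert theory.architecture_density_scaling(100, 1000) == pytest.approx(10.0)
        assert theory.architecture_density_scaling(5, 5) == 1.0


class TestStructureLD:
    def test_stratification_values(self):
        D, Dt = theory.stratification_ld([0.5, 0.7], [0.5, 0.5])
        assert D[0, 1] == 0.0
        D, Dt = theory.stratification_ld([0.6, 0.6], [0.4, 0.4])
        assert D[0, 1] == pytest.approx(0.25 * 0.04)
        assert np.allclose(D, Dt)

    def test_admixture_trajectory(self):
        c = np.array([[0.0, 0.5], [0.5, 0.0]])
        D0, T0 = theory.admixture_ld_trajectory([0.6, 0.6], [0.4, 0.4], 0.5, c, 0)
        assert D0[0, 1] == pytest.approx(0.25 * 0.04)
        assert np.allclose(D0, T0)  # at t=0 the mixture is maximally structured
        D3, T3 = theory.admixture_ld_trajectory([0.6, 0.6], [0.4, 0.4], 0.5, c, 3)
        assert D3[0, 1] == pytest.approx(D0[0, 1] / 8)
        assert np.all(T3 == 0.0)

    def test_degenerate_admixture_proportions(self):
        c = np.zeros((2, 2))
        for A in (0.0, 1.0):
            D, _ = theory.admixture_ld_trajectory([0.6, 0.6], [0.4, 0.4], A, c, 0)
            assert np.all(D == 0.0)


class TestBulmer:
    @pytest.fixture(scope="class")
    @staticmethod
    def height():
        return theory.solve_bulmer_observed(0.8, 30.0, 0.464, n_loci=1000)

    def test_height_attenuations(self, height):
        att = theory.bulmer_attenuation(state=height)
        assert 100 * att["pre_pop"] == pytest.approx(2.7, abs=0.1)
        assert 100 * att["post_pop"] == pytest.approx(5.2, abs=0.1)
        assert 100 * att["family"] == pytest.approx(0.2, abs=0.1)

    def test_design_ratios(self, height):
        att = theory.bulmer_attenuation(state=height)
        assert att["family_over_pre"] == pytest.approx(0.072, abs=1e-12)
        assert att["family_over_post"] == pytest.approx(0.037, abs=0.001)

    def test_fixed_point_consistent_with_observed_closed_form(self, height):
        st = theory.solve_bulmer(height.V_g, height.V_E, 30.0, 0.464)
        assert st.d_star == pytest.approx(height.d_star, rel=1e-8)
        assert st.h2 == pytest.approx(0.8, abs=1e-9)

    def test_neutral_limit(self):
        st = theory.solve_bulmer_observed(0.8, 1e9, 0.464)
        assert abs(st.d_star) < 1e-9

    def test_monotone_in_selection_strength_and_heritability(self):
        """Attenuation grows as selection strengthens or h2 rises."""
        grid_vs = [20, 40, 80, 160]
        pre = [theory.bulmer_attenuation(
            state=theory.solve_bulmer_observed(0.8, v, 0.464))["pre_pop"]
            for v in grid_vs]
        assert all(a > b for a, b in zip(pre, pre[1:]))
        grid_h2 = [0.4, 0.6, 0.8, 1.0]
        pre = [theory.bulmer_attenuation(
            state=theory.solve_bulmer_observed(h, 30, 0.464))["pre_pop"]
            for h in grid_h2]
        assert all(a < b for a, b in zip(pre, pre[1:]))

    def test_masked_mate_correlation_height(self, height):
        assert theory.masked_am_correlation(0.25, height, "pre") == pytest.approx(0.20, abs=0.001)
        assert theory.masked_am_correlation(0.25, height, "post") == pytest.approx(0.15, abs=0.001)

    def test_masking_vanishes_without_selection(self):
        st = theory.solve_bulmer_observed(0.8, 1e12, 0.464)
        assert theory.masked_am_correlation(0.25, st, "pre") == pytest.approx(0.25, abs=1e-9)
        assert theory.masked_am_correlation(0.25, st, "post") == pytest.approx(0.25, abs=1e-9)

    def test_masked_fraction_grows_when_am_weaker_or_selection_stronger(self):
        st = theory.solve_bulmer_observed(0.8, 30, 0.464)
        frac = lambda rho, s: 1 - theory.masked_am_correlation(rho, s, "pre") / rho
        assert frac(0.15, st) > frac(0.25, st)
        stronger = theory.solve_bulmer_observed(0.8, 20, 0.464)
        assert frac(0.25, stronger) > frac(0.25, st)


class TestSiblingIndirectForms:
    def test_beta_zero(self):
        sib, pop = theory.sibling_indirect_bias(1.3, 0.0, 0.5)
        assert sib == pop == 1.3

    def test_worked_values(self):
        sib, pop = theory.sibling_indirect_bias(1.0, 0.2, 0.5)
        assert sib == pytest.approx(1 / 1.2)
        assert pop == pytest.approx(1.1 / 0.96)

    def test_antagonistic_effects_overestimate(self):
        sib, _ = theory.sibling_indirect_bias(1.0, -0.4, 0.5)
        assert sib > 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            theory.sibling_indirect_bias(1.0, -1.0, 0.5)
        sib, pop = theory.sibling_indirect_bias(1.0, 1.0, 0.5)
        assert sib == pytest.approx(0.5) and np.isnan(pop)

    @given(st.floats(-0.9, 0.9), st.floats(0.1, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_population_form_consistent_with_feedback_algebra(self, beta, alpha):
        """Eq-by-construction check: (alpha + alpha beta r)/(1 - beta^2)."""
        sib, pop = theory.sibling_indirect_bias(alpha, beta, 0.5)
        assert sib == pytest.approx(alpha / (1 + beta))
        assert pop == pytest.approx(alpha * (1 + 0.5 * beta) / (1 - beta**2))
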
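"""Growth-rate quadratic, root selection and balanced-growth ratios."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ptrcell as pc

from conftest import params_strategy


class TestQuadraticCoefficients:
    def test_reference_medium_half_allocation(self, caption_params):
        c = pc.quadratic_coefficients(caption_params.replace(f_R=0.5))
        assert c.nu == pytest.approx(0.5)
        assert c.rho == pytest.approx(5.0)
        assert c.a == pytest.approx(0.5 * 0.5 - 0.1)
        assert c.b == pytest.approx(2.5)

    def test_full_ribosomal_allocation_zeroes_gamma(self):
        p = pc.baseline_parameters(d_T=0.0, d_R=0.0, f_R=1.0)
        c = pc.quadratic_coefficients(p)
        assert c.a == 0.0
        assert c.gamma == 0.0

    def test_zero_protein_volumes_drop_corrections(self,
                                                   precursor_volume_params):
        c = pc.quadratic_coefficients(precursor_volume_params)
        assert c.eps1 == 0.0 and c.eps2 == 0.0
        assert c.alpha == 1.0
        assert c.beta == c.a + c.b


class TestSolveGrowthRate:
    def test_symmetric_closed_form(self):
        # nu = rho = 1, f_R = 1/2, equal volumes, m = 1e4:
        # beta = 1, gamma = 1/4, alpha = 1 - 1e-4
        m = 1e4
        p = pc.PTRParameters(K_P=m, k=m * 1e-8, m_T=m, m_R=m,
                             v_P=1e-8, v_T=1e-8, v_R=1e-8, f_R=0.5)
        expected = (1.0 - math.sqrt(1e-4)) / (2.0 * (1.0 - 1e-4))
        roots = pc.solve_growth_rate(p)
        assert roots.mu_minus == pytest.approx(expected, rel=1e-12)

    @given(params_strategy())
    def test_roots_match_generic_polynomial_solver(self, p):
        """Stable two-root formula agrees with numpy's companion-matrix
        eigenvalue solver on alpha mu^2 - beta mu + gamma."""
        c = pc.quadratic_coefficients(p)
        roots = pc.solve_growth_rate(p)
        if not roots.feasible or roots.degenerate:
            return
        ref = np.sort(np.roots([c.alpha, -c.beta, c.gamma]))
        ours = np.sort([roots.mu_minus, roots.mu_plus])
        np.testing.assert_allclose(ours, ref, rtol=1e-6, atol=1e-12)
        if c.well_posed:
            # with alpha > 0 the physical branch is the smaller root
            assert roots.mu_minus == pytest.approx(ref[0], rel=1e-6,
                                                   abs=1e-12)

    def test_allocation_limits_kill_growth(self):
        """Without degradation mu_- vanishes as f_R -> 0 (no new ribosomes)
        and as f_R -> 1 (no new transporters)."""
        for f_R in (1e-8, 1.0 - 1e-8):
            p = pc.baseline_parameters(d_T=0.0, d_R=0.0, f_R=f_R)
            assert abs(pc.solve_growth_rate(p).mu_minus) < 1e-6

    def test_zero_gamma_gives_zero_root(self):
        p = pc.baseline_parameters(d_T=0.0, d_R=0.0, f_R=1.0)
        assert pc.solve_growth_rate(p).mu_minus == 0.0

    def test_complex_roots_reported_infeasible(self):
        # strongly degrading regime dominated by volume corrections:
        # a < 0, b < 0 with eps2 ~ |a+b| pushes the discriminant negative
        p = pc.PTRParameters(K_P=0.00106, k=8.33e-6, m_T=1, m_R=4, d_T=0.5,
                             d_R=2.5, v_P=1e-6, v_T=1e-6, v_R=0.0, f_R=0.06)
        roots = pc.solve_growth_rate(p)
        assert roots.discriminant < 0
        assert not roots.feasible
        assert math.isnan(roots.mu_minus)

    def test_degenerate_alpha_linear_fallback(self):
        # eps1 = 1 exactly: (f_T/m_T)(v_T/v_P) = 1 with f_R=0, m_T=1, v_T=v_P
        p = pc.PTRParameters(K_P=10, k=1e-4, m_T=1, m_R=10, d_T=0.0,
                             d_R=0.0, v_P=1e-8, v_T=1e-8, v_R=0.0, f_R=0.0)
        roots = pc.solve_growth_rate(p)
        assert roots.degenerate
        c = pc.quadratic_coefficients(p)
        assert roots.mu_minus == pytest.approx(c.gamma / c.beta)


class TestSteadyRatios:
    def test_equal_degradation_makes_fraction_equal_allocation(self):
        p = pc.baseline_parameters(d_T=0.1, d_R=0.1, f_R=0.3)
        ss = pc.steady_ratios(p, 0.7)
        assert ss.Phi_R == pytest.approx(0.3, rel=1e-12)

    def test_transporter_ribosome_ratio_at_optimum(self, caption_params):
        """Substituting the large-m optimum (f_max, mu_max) into the
        balanced T/R expression gives (m_R/m_T)(rho/nu) = 200."""
        f_max = pc.fmax_large_m(caption_params)
        mu_max = pc.mumax_large_m(caption_params)
        ss = pc.steady_ratios(caption_params.replace(f_R=f_max), mu_max)
        assert ss.T_over_R == pytest.approx(200.0, rel=1e-12)
        assert ss.Phi_R == pytest.approx(0.5 / 5.5, rel=1e-12)

    def test_marginal_feasibility_zero_precursor(self, caption_params):
        """When production exactly covers dilution+degradation of T the
        precursor pool empties: P/R = 0."""
        p = caption_params.replace(f_R=0.5)
        # choose mu so that K_P f_T / (m_T (mu + d_T)) = 1
        mu = p.K_P * p.f_T / p.m_T - p.d_T
        ss = pc.steady_ratios(p, mu)
        assert ss.P_over_R == pytest.approx(0.0, abs=1e-9)
        assert ss.feasible

    def test_zero_growth_without_ribosome_turnover_is_flagged(self,
                                                              caption_params):
        ss = pc.steady_ratios(caption_params.replace(d_R=0.0), 0.0)
        assert not ss.feasible
        assert "P/R undefined" in ss.reason

    def test_zero_allocation_flagged(self, caption_params):
        ss = pc.steady_ratios(caption_params.replace(f_R=0.0), 0.3)
        assert not ss.feasible


class TestRibosomalFraction:
    def test_boundary_values(self, caption_params):
        assert pc.ribosomal_fraction(caption_params.replace(f_R=1.0), 0.5) == 1.0
        assert pc.ribosomal_fraction(caption_params.replace(f_R=0.0), 0.5) == 0.0

    def test_reference_optimum_value(self, caption_params):
        p = caption_params.replace(f_R=0.0727)
        assert pc.ribosomal_fraction(p, 0.3636) == pytest.approx(
            0.0909, abs=5e-5)

    @given(params_strategy(), st.floats(1e-3, 10.0))
    def test_both_algebraic_forms_agree(self, p, mu):
        """The closed form and its partial-fraction rearrangement agree to
        1e-12 relative (asserted internally)."""
        phi = pc.ribosomal_fraction(p, mu)
        assert 0.0 <= phi <= 1.0


class TestConsistency:
    def test_balanced_state_satisfies_original_equations(
            self, random_growing_sets):
        """mu_- plus the closed-form ratios reproduce all three population
        equations with relative residuals below 1e-10."""
        for p in random_growing_sets:
            ss = pc.balanced_state(p)
            assert ss.feasible
            assert max(pc.ansatz_residuals(p, ss)) < 1e-10

    def test_larger_root_implies_negative_populations(self):
        """At zero degradation and huge identical residue counts the
        unphysical root mu_+ forces P < 0 while mu_- gives P > 0."""
        m = 1e6
        rng = np.random.default_rng(42)
        for f_R in rng.uniform(0.05, 0.95, 10):
            p = pc.PTRParameters(K_P=0.8 * m, k=3 * m * 1e-8, m_T=m, m_R=m,
                                 d_T=0.0, d_R=0.0, v_P=1e-8, v_T=1e-8,
                                 v_R=1e-8, f_R=float(f_R))
            roots = pc.solve_growth_rate(p)
            assert pc.steady_ratios(p, roots.mu_minus).P_over_R > 0
            assert pc.steady_ratios(p, roots.mu_plus).P_over_R < 0
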
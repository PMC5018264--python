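"""Medium models, Monod constants, phenomenological constants and sweeps."""

import numpy as np
import pytest

import ptrcell as pc


class TestMediumModel:
    def test_linear_form(self):
        m = pc.MediumModel(form="linear", k1=2.0)
        assert pc.nu_from_medium(m, 0.25) == pytest.approx(0.5)
        assert pc.nu_from_medium(m, 0.0) == 0.0

    def test_michaelis_menten_half_saturation(self):
        m = pc.MediumModel(form="michaelis_menten", nu0=4.0, K=1.5)
        assert pc.nu_from_medium(m, 1.5) == pytest.approx(2.0)
        assert pc.nu_from_medium(m, 0.0) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            pc.nu_from_medium(pc.MediumModel(form="linear", k1=1.0), -1.0)

    def test_invalid_forms_rejected(self):
        with pytest.raises(ValueError):
            pc.MediumModel(form="hill", k1=1.0)
        with pytest.raises(ValueError):
            pc.MediumModel(form="linear")


class TestMonodConstants:
    def test_linear_uptake(self):
        m = pc.MediumModel(form="linear", k1=2.0)
        mu_inf, C1 = pc.monod_constants(m, rho=5.0)
        assert mu_inf == pytest.approx(5.0)
        assert C1 == pytest.approx(2.5)

    def test_transport_limited_symmetric_point(self):
        m = pc.MediumModel(form="michaelis_menten", nu0=5.0, K=2.0)
        mu_inf, C1 = pc.monod_constants(m, rho=5.0)
        assert mu_inf == pytest.approx(2.5)
        assert C1 == pytest.approx(1.0)

    def test_degradation_unsupported(self):
        m = pc.MediumModel(form="linear", k1=2.0)
        with pytest.raises(pc.UnsupportedCaseError):
            pc.monod_constants(m, rho=5.0, d_T=0.1)

    def test_exact_monod_reproduction(self):
        """Optimized growth over a food grid is exactly hyperbolic when
        degradation vanishes and uptake is linear in [F]."""
        base = pc.baseline_parameters(d_T=0.0, d_R=0.0)
        medium = pc.MediumModel(form="linear", k1=2.0)
        mu_inf, C1 = pc.monod_constants(medium, rho=base.rho)
        F = np.linspace(0.01, 20.0, 100)
        curve = pc.monod_curve(base, medium, F)
        expected = mu_inf * F / (C1 + F)
        assert np.max(np.abs(curve["mu_max"].to_numpy() - expected)
                      / expected) < 1e-10

    def test_efficiency_interchange_plateau(self):
        """Holding nu fixed and sweeping rho mirrors the Monod curve: the
        plateau is nu and half-saturation occurs at rho = nu."""
        nu = 0.5
        base = pc.baseline_parameters(d_T=0.0, d_R=0.0)  # nu = 0.5
        half = base.replace(k=nu * base.m_R * base.v_P)  # rho = nu
        assert pc.mumax_large_m(half) == pytest.approx(nu / 2)
        plateau = base.replace(k=1e6 * nu * base.m_R * base.v_P)
        assert pc.mumax_large_m(plateau) == pytest.approx(nu, rel=1e-5)


class TestPhenomenologicalConstants:
    def test_reference_values(self, caption_params):
        c = pc.phenomenological_constants(caption_params)
        assert c.Phi_R_min == pytest.approx(0.1 / 5.1)
        assert c.kappa_t == pytest.approx(5.1)
        assert c.Phi_R_max == pytest.approx(1.0)
        assert c.kappa_n == pytest.approx(0.4)
        assert c.valid

    def test_zero_degradation_limits(self):
        no_dT = pc.baseline_parameters(d_T=0.0, d_R=0.01)
        assert pc.phenomenological_constants(no_dT).Phi_R_min == 0.0
        no_dR = pc.baseline_parameters(d_T=0.1, d_R=0.0)
        assert pc.phenomenological_constants(no_dR).Phi_R_max == 1.0

    def test_equal_degradation_recovers_simple_slopes(self):
        p = pc.baseline_parameters(d_T=0.07, d_R=0.07)
        c = pc.phenomenological_constants(p)
        assert c.kappa_t == pytest.approx(p.rho)
        assert c.kappa_n == pytest.approx(p.nu)

    def test_invalid_regime_flagged_not_raised(self):
        p = pc.baseline_parameters(q=0.1, d_T=0.2, d_R=0.0)  # nu < d_T
        c = pc.phenomenological_constants(p)
        assert not c.valid and c.notes


class TestSweeps:
    def test_single_point_sweep(self, precursor_volume_params):
        table = pc.sweep_medium_quality(precursor_volume_params, [2.0])
        assert len(table) == 1
        with pytest.raises(ValueError):
            pc.fit_growth_law(table["mu_max"], table["Phi_R"], "nutritional")

    def test_quality_sweep_recovers_nutritional_line(
            self, precursor_volume_params):
        table = pc.sweep_medium_quality(precursor_volume_params,
                                        [1.0, 2.0, 4.0, 8.0])
        fit = pc.fit_growth_law(table["mu_max"], table["Phi_R"],
                                "nutritional")
        c = pc.phenomenological_constants(precursor_volume_params)
        assert fit.slope > 0
        assert fit.r_squared > 1 - 1e-6
        assert fit.Phi_R_min == pytest.approx(c.Phi_R_min, rel=1e-2)
        assert fit.kappa_t == pytest.approx(c.kappa_t, rel=1e-2)

    def test_efficiency_sweep_recovers_translational_line(
            self, precursor_volume_params):
        table = pc.sweep_ribosomal_efficiency(precursor_volume_params)
        fit = pc.fit_growth_law(table["mu_max"], table["Phi_R"],
                                "translational")
        c = pc.phenomenological_constants(precursor_volume_params)
        assert fit.slope < 0
        assert fit.Phi_R_max == pytest.approx(c.Phi_R_max, rel=1e-2)
        assert fit.kappa_n == pytest.approx(c.kappa_n, rel=1e-2)

    def test_large_m_columns_fit_exactly(self, caption_params):
        """The closed-form (mu_max, Phi_R) pairs lie exactly on the
        growth-law line whatever the volume constants."""
        table = pc.sweep_medium_quality(caption_params, [1.0, 2.0, 4.0, 8.0])
        fit = pc.fit_growth_law(table["mu_max_large_m"],
                                table["Phi_R_large_m"], "nutritional")
        c = pc.phenomenological_constants(caption_params)
        assert fit.r_squared > 1 - 1e-12
        assert fit.kappa_t == pytest.approx(c.kappa_t, rel=1e-9)
        assert fit.Phi_R_min == pytest.approx(c.Phi_R_min, rel=1e-9)

    def test_lower_efficiency_steepens_nutritional_line(
            self, precursor_volume_params):
        slopes = []
        for k in (precursor_volume_params.k, precursor_volume_params.k / 4):
            p = precursor_volume_params.replace(k=k)
            t = pc.sweep_medium_quality(p, [1.0, 2.0, 4.0, 8.0])
            slopes.append(pc.fit_growth_law(t["mu_max"], t["Phi_R"],
                                            "nutritional").slope)
        assert slopes[1] > slopes[0]

    def test_quality_sweep_saturates_toward_rho(self, precursor_volume_params):
        """mu_max(q) increases and approaches the ribosomal-efficiency
        plateau as the medium becomes rich (d_R = 0)."""
        table = pc.sweep_medium_quality(precursor_volume_params,
                                        np.geomspace(1, 1e4, 6))
        mu = table["mu_max"].to_numpy()
        assert (np.diff(mu) > 0).all()
        assert mu[-1] < precursor_volume_params.rho
        assert mu[-1] == pytest.approx(precursor_volume_params.rho, rel=1e-2)

    def test_invalid_grids_rejected(self, precursor_volume_params):
        with pytest.raises(ValueError):
            pc.sweep_medium_quality(precursor_volume_params, [0.0, 1.0])
        with pytest.raises(ValueError):
            pc.sweep_ribosomal_efficiency(precursor_volume_params, [-1.0])
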
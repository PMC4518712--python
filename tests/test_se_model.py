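"""Sedimentation-equilibrium physics, global fitting and error analysis."""

import math

import numpy as np
import pytest

from assocfit.equilibria import AssociationScheme
from assocfit.se import (
    DegenerateBuoyancyError,
    SEChannel,
    SEGlobalFitter,
    SolutionProperties,
    SvCorrectionInput,
    _implied_loading,
    conserve_mass,
    correct_s20w,
    reduced_buoyant_sigma,
    se_profile,
)
from assocfit import synthetic as synth


@pytest.fixture()
def props84():
    return SolutionProperties(monomer_mass=84_000.0)


class TestReducedBuoyantSigma:
    def test_hand_computed_value(self, props84):
        # M=84 kDa, v̄=0.73, ρ=1.005, 11.8 krpm, 293.15 K in cgs units
        assert reduced_buoyant_sigma(props84, 11_800.0) == pytest.approx(1.402, abs=0.01)

    def test_quadratic_in_rotor_speed(self, props84):
        s1 = reduced_buoyant_sigma(props84, 10_000.0)
        s2 = reduced_buoyant_sigma(props84, 20_000.0)
        assert s2 == pytest.approx(4.0 * s1, rel=1e-12)

    def test_degenerate_buoyancy_raises(self):
        props = SolutionProperties(monomer_mass=84_000.0, vbar=1.0, density=1.0)
        with pytest.raises(DegenerateBuoyancyError):
            reduced_buoyant_sigma(props, 10_000.0)


class TestSEProfile:
    def test_zero_sigma_gives_flat_profile(self, props84):
        scheme = AssociationScheme((1, 2), (1e-5,))
        radii = np.linspace(6.96, 7.24, 50)
        prof = se_profile(scheme, 0.0, 6.95, 5e-6, radii, 0.01, props84)
        expected = 0.01 + props84.signal_per_molar * (5e-6 + 2 * (5e-6) ** 2 / 1e-5)
        assert np.allclose(prof, expected, rtol=1e-12)

    def test_single_species_log_linear_in_r_squared(self, props84):
        scheme = AssociationScheme((1,), ())
        radii = np.linspace(6.96, 7.24, 200)
        sigma1 = 1.4
        prof = se_profile(scheme, sigma1, 6.95, 5e-6, radii, 0.0, props84)
        slope = np.polyfit(radii**2, np.log(prof), 1)[0]
        assert slope == pytest.approx(sigma1 / 2.0, rel=1e-9)

    def test_monomer_dimer_matches_per_point_sum_of_exponentials(self, props84):
        kd, m0, sigma1, r0 = 7e-6, 4e-6, 1.5, 6.95
        scheme = AssociationScheme((1, 2), (kd,))
        radii = np.array([6.97, 7.05, 7.21])
        prof = se_profile(scheme, sigma1, r0, m0, radii, 0.002, props84)
        for r, p in zip(radii, prof):
            mono = m0 * math.exp(sigma1 * (r**2 - r0**2) / 2.0)
            dim = (m0**2 / kd) * math.exp(2.0 * sigma1 * (r**2 - r0**2) / 2.0)
            expected = 0.002 + props84.signal_per_molar * (mono + 2.0 * dim)
            assert p == pytest.approx(expected, rel=1e-12)


class TestConserveMass:
    def _channel(self):
        radii = np.linspace(6.96, 7.24, 30)
        return SEChannel(
            radii=radii, signal=np.ones_like(radii), rotor_speed=11_800.0,
            loading_signal=0.9,
        )

    def test_flat_profile_returns_loading_exactly(self):
        scheme = AssociationScheme((1,), ())
        ch = self._channel()
        assert conserve_mass(ch, scheme, 0.0, 6.95, 5e-6) == pytest.approx(
            5e-6, rel=1e-12
        )

    def test_quadrature_matches_symbolic_integration(self):
        # independent oracle: sympy's symbolic sector integral
        sympy = pytest.importorskip("sympy")
        scheme = AssociationScheme((1, 2), (7e-6,))
        ch = self._channel()
        sigma1, r0, m0 = 1.4, 6.95, 4e-6
        r = sympy.Symbol("r")
        total = 0.0
        for n, c in [(1, m0), (2, m0**2 / 7e-6)]:
            integrand = n * c * sympy.exp(n * sigma1 * (r**2 - r0**2) / 2) * r
            val = sympy.integrate(integrand, (r, ch.meniscus, ch.bottom))
            total += float(val)
        expected = 2.0 * total / (ch.bottom**2 - ch.meniscus**2)
        got = conserve_mass(ch, scheme, sigma1, r0, m0)
        assert got == pytest.approx(expected, rel=1e-9)
        # and the fitter's closed-form path agrees with the quadrature path
        closed = _implied_loading(scheme, sigma1, r0, m0, ch.meniscus, ch.bottom)
        assert closed == pytest.approx(got, rel=1e-9)


class TestGlobalFit:
    def test_zero_noise_round_trip_monomer_dimer(self):
        design = synth.SEDesign(noise_sigma=0.0)
        exp = synth.gen_se(7e-6, seed=1, design=design)
        fit = SEGlobalFitter().fit(exp)
        assert abs(fit.log10_kd_[0] - math.log10(7e-6)) < 1e-4
        assert max(abs(b) for b in fit.baselines_) < 1e-8

    def test_zero_noise_round_trip_monomer_dimer_tetramer(self):
        design = synth.SEDesign(noise_sigma=0.0)
        exp = synth.gen_se(
            (1e-5, 1e-15), seed=1, scheme_stoich=(1, 2, 4), design=design
        )
        fit = SEGlobalFitter().fit(exp)
        assert abs(fit.log10_kd_[0] - math.log10(1e-5)) < 1e-4
        assert abs(fit.log10_kd_[1] - math.log10(1e-15)) < 1e-4

    def test_monomer_only_data_pushes_kd_beyond_loadings(self):
        # non-associating sample fitted with a monomer–dimer scheme: the
        # recovered constant must exceed 100x the top loading concentration
        from assocfit.se import SEExperiment

        design = synth.SEDesign(noise_sigma=0.003)
        exp_mono = synth.gen_se((), seed=2, scheme_stoich=(1,), design=design)
        exp = SEExperiment(
            exp_mono.channels, exp_mono.properties, AssociationScheme((1, 2), (1e-5,))
        )
        with pytest.warns(RuntimeWarning):
            fit = SEGlobalFitter().fit(exp)
        top_loading = max(
            ch.loading_signal for ch in exp.channels
        ) / exp.properties.signal_per_molar
        assert fit.kd_[0] > 100.0 * top_loading
        assert fit.result_.at_boundary

    def test_single_species_data_is_log_linear(self):
        design = synth.SEDesign(noise_sigma=0.0)
        exp = synth.gen_se((), seed=3, scheme_stoich=(1,), design=design)
        ch = exp.channels[0]
        r2 = ch.radii**2
        lny = np.log(ch.signal)
        fit = np.polyfit(r2, lny, 1)
        resid = lny - np.polyval(fit, r2)
        r_squared = 1.0 - np.sum(resid**2) / np.sum((lny - lny.mean()) ** 2)
        assert r_squared > 0.9999

    def test_reduced_chi2_matches_noise_over_seeds(self, full_length_se_fits):
        med = np.median([f.reduced_chi2_ for f in full_length_se_fits])
        assert 0.8 <= med <= 1.2

    def test_mass_conservation_holds_for_reported_fit(self, full_length_se_fits):
        fit = full_length_se_fits[0]
        exp = fit._experiment
        scheme = AssociationScheme(exp.scheme.stoichiometries, fit.kd_)
        for ch, m0 in zip(exp.channels, fit.ref_monomer_):
            sigma1 = reduced_buoyant_sigma(exp.properties, ch.rotor_speed)
            implied = conserve_mass(ch, scheme, sigma1, ch.meniscus, m0)
            known = ch.loading_signal / exp.properties.signal_per_molar
            assert abs(implied - known) / known < 1e-8


class TestMonteCarlo:
    def test_zero_iterations_leaves_result_unchanged(self):
        design = synth.SEDesign(noise_sigma=0.004)
        exp = synth.gen_se(7e-6, seed=4, design=design)
        fitter = SEGlobalFitter().fit(exp)
        res = fitter.monte_carlo_ci(n_iter=0)
        assert res.kd_ci is None and res.n_monte_carlo == 0

    def test_vanishing_noise_collapses_ci(self):
        design = synth.SEDesign(noise_sigma=0.0)
        exp = synth.gen_se(7e-6, seed=5, design=design)
        fitter = SEGlobalFitter().fit(exp)
        res = fitter.monte_carlo_ci(n_iter=5, seed=1)
        lo, hi = res.kd_ci[0]
        assert (hi - lo) / res.kd_estimates[0] < 1e-4

    def test_seeded_determinism(self):
        design = synth.SEDesign(noise_sigma=0.005)
        exp = synth.gen_se(7e-6, seed=6, design=design)
        f1 = SEGlobalFitter().fit(exp)
        r1 = f1.monte_carlo_ci(n_iter=10, seed=42)
        f2 = SEGlobalFitter().fit(exp)
        r2 = f2.monte_carlo_ci(n_iter=10, seed=42)
        assert r1.kd_ci == r2.kd_ci


class TestS20wCorrection:
    def test_water_at_20C_is_identity(self):
        inp = SvCorrectionInput(
            s_observed=4.0, buffer_density=0.99823, buffer_viscosity=1.002, vbar=0.73
        )
        assert correct_s20w(inp) == pytest.approx(4.0, rel=1e-12)

    def test_hand_computed_correction(self):
        # buoyancy terms: 1 − 0.73·0.99823 = 0.2712921 (water),
        # 1 − 0.73·1.005 = 0.26635 (buffer)
        inp = SvCorrectionInput(
            s_observed=4.0, buffer_density=1.005, buffer_viscosity=1.05, vbar=0.73
        )
        expected = 4.0 * (1.05 / 1.002) * (0.2712921 / 0.26635)
        assert correct_s20w(inp) == pytest.approx(expected, rel=1e-6)

    def test_linear_in_inverse_buffer_buoyancy(self):
        # halving (1 − v̄ρ)_buffer doubles s20,w: choose densities so the
        # buoyancy term halves exactly
        vbar = 0.73
        rho1 = (1.0 - 0.2) / vbar  # buoyancy 0.2
        rho2 = (1.0 - 0.1) / vbar  # buoyancy 0.1
        s1 = correct_s20w(SvCorrectionInput(4.0, rho1, 1.0, vbar))
        s2 = correct_s20w(SvCorrectionInput(4.0, rho2, 1.0, vbar))
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)


class TestChannelValidation:
    def test_geometry_and_length_checks(self):
        radii = np.linspace(6.96, 7.24, 30)
        with pytest.raises(ValueError):
            SEChannel(radii, np.ones(30), 11_800.0, 0.9, meniscus=7.0)
        with pytest.raises(ValueError):
            SEChannel(radii[:10], np.ones(10), 11_800.0, 0.9)
        with pytest.raises(ValueError):
            SEChannel(radii[::-1], np.ones(30), 11_800.0, 0.9)
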
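"""Causal-filter information rates: SNRs, limits, dual solvers, efficiency."""

import numpy as np
import pytest
from dataclasses import replace

from chemoinfo.information import (
    BERG_PURCELL_THRESHOLD,
    berg_purcell_check,
    efficiency_eta,
    gamma_a,
    gamma_r,
    info_rate_from_rho,
    noise_psd_components,
    population_eta_percentiles,
    solve_kinase_filter,
    solve_physical_limit_filter,
)
from chemoinfo.models import Environment, KinasePhenotype


G_MM = 1e-3  # conversion mm^-1 -> um^-1


class TestSNRs:
    def test_gamma_r_printed_value(self, published):
        swim, _, env = published
        assert gamma_r(env, swim, 0.05 * G_MM) == pytest.approx(0.15, abs=0.01)

    def test_gamma_r_steep(self, published):
        swim, _, env = published
        assert gamma_r(env, swim, 0.4 * G_MM) == pytest.approx(9.4, rel=0.02)

    def test_gamma_zero_gradient(self, published):
        swim, kin, env = published
        assert gamma_r(env, swim, 0.0) == 0.0
        assert gamma_a(env, swim, kin, 0.0) == 0.0

    def test_gamma_ratio(self, published):
        # gamma_r/gamma_a = 2 tau_v^2 D_n / (G_r^2 r0) ~ 53 at c0 = 1 uM
        swim, kin, env = published
        ratio = gamma_r(env, swim, 5e-5) / gamma_a(env, swim, kin, 5e-5)
        expect = 2 * swim.tau_v**2 * kin.D_n / (kin.G_r**2 * env.r0)
        assert ratio == pytest.approx(expect, rel=1e-9)
        assert ratio == pytest.approx(53.0, rel=0.02)

    def test_gain_scaling(self, published):
        swim, kin, env = published
        kin2 = replace(kin, G_r=2 * kin.G_r)
        assert gamma_a(env, swim, kin2, 1e-4) == pytest.approx(
            4 * gamma_a(env, swim, kin, 1e-4))

    def test_noiseless_sensor_branch(self, published):
        swim, kin, env = published
        with pytest.raises(ZeroDivisionError):
            gamma_a(env, swim, replace(kin, D_n=0.0), 1e-4)


class TestPhysicalLimitFilter:
    def test_small_signal_form(self, published):
        # Idot_r -> gamma_r/(4 tau_v) as gamma_r -> 0
        swim, _, env = published
        g = 1e-7
        sol = solve_physical_limit_filter(env, swim, g)
        assert sol.info_rate == pytest.approx(
            gamma_r(env, swim, g) / (4 * swim.tau_v), rel=0.01)

    def test_zero_gradient(self, published):
        swim, _, env = published
        sol = solve_physical_limit_filter(env, swim, 0.0)
        assert sol.rho2 == 0.0 and sol.info_rate == 0.0

    def test_posterior_variance_identity(self, published):
        swim, _, env = published
        sol = solve_physical_limit_filter(env, swim, 2e-4)
        sigma_s2 = (2e-4) ** 2 * swim.sigma_v2
        assert sol.posterior_var == pytest.approx(
            sigma_s2 * (1 - sol.rho2), rel=1e-9)

    def test_leak_insensitivity(self, published):
        swim, _, env = published
        a = solve_physical_limit_filter(env, swim, 2e-4, integrator_leak=0.0)
        b = solve_physical_limit_filter(env, swim, 2e-4,
                                        integrator_leak=1e-8 / swim.tau_v)
        assert a.posterior_var == pytest.approx(b.posterior_var, rel=1e-6)


class TestDualSolvers:
    def test_riccati_vs_spectral_grid(self, published):
        # independent solution routes agree to 1e-6 relative on a 10x10 grid
        swim, kin, env1 = published
        leak = 1e-8 / swim.tau_v
        c0s = np.logspace(-1, 1, 10)
        gs = np.linspace(0.02, 0.4, 10) * G_MM
        for c0 in c0s:
            env = Environment(c0=float(c0), k_D=env1.k_D)
            for g in gs:
                a = solve_physical_limit_filter(env, swim, g,
                                                method="riccati",
                                                integrator_leak=leak)
                b = solve_physical_limit_filter(env, swim, g,
                                                method="spectral",
                                                integrator_leak=leak)
                assert b.posterior_var == pytest.approx(a.posterior_var,
                                                        rel=1e-6)

    def test_riccati_vs_spectral_kinase(self, published):
        swim, kin, env1 = published
        leak = 1e-8 / swim.tau_v
        for c0 in (0.1, 1.0, 10.0):
            env = Environment(c0=c0, k_D=env1.k_D)
            for g_mm in (0.02, 0.1, 0.4):
                a = solve_kinase_filter(env, swim, kin, g_mm * G_MM,
                                        method="riccati",
                                        integrator_leak=leak)
                b = solve_kinase_filter(env, swim, kin, g_mm * G_MM,
                                        method="spectral",
                                        integrator_leak=leak)
                assert b.posterior_var == pytest.approx(a.posterior_var,
                                                        rel=1e-6)


class TestKinaseFilter:
    def test_noiseless_kinase_attains_physical_limit(self, published):
        # D_n -> 0 (gamma_a -> infinity) recovers Idot_r
        swim, kin, env = published
        kin0 = replace(kin, D_n=1e-12)
        for g_mm in (0.05, 0.4):
            i_a = solve_kinase_filter(env, swim, kin0, g_mm * G_MM).info_rate
            i_r = solve_physical_limit_filter(env, swim, g_mm * G_MM).info_rate
            assert i_a == pytest.approx(i_r, rel=0.01)

    def test_internal_noise_dominated_limit(self, published):
        # gamma_a/gamma_r -> 0 with slow adaptation/noise: Idot_a -> gamma_a/(4 tau_v)
        swim, kin, env = published
        kin_slow = replace(kin, D_n=kin.D_n * 1e6, tau_2=100 * swim.tau_v,
                           tau_n=100 * swim.tau_v)
        g = 5e-5
        i_a = solve_kinase_filter(env, swim, kin_slow, g).info_rate
        ga = gamma_a(env, swim, kin_slow, g)
        assert i_a == pytest.approx(ga / (4 * swim.tau_v), rel=0.01)

    def test_zero_gradient(self, published):
        swim, kin, env = published
        assert solve_kinase_filter(env, swim, kin, 0.0).info_rate == 0.0

    def test_data_processing_inequality_grid(self, published):
        swim, kin, env1 = published
        for c0 in (0.1, 0.5, 1.0, 3.0, 10.0):
            env = Environment(c0=c0, k_D=env1.k_D)
            for g_mm in (0.01, 0.05, 0.1, 0.2, 0.4):
                i_a = solve_kinase_filter(env, swim, kin, g_mm * G_MM).info_rate
                i_r = solve_physical_limit_filter(env, swim, g_mm * G_MM).info_rate
                assert i_a < i_r  # strict when D_n > 0

    def test_small_signal_efficiency_matches_snr_form(self, published):
        # eta(g->0) = (u/(1+u))^2 with u = sqrt(gamma_a/gamma_r)
        swim, kin, env = published
        g = 1e-6
        u = np.sqrt(gamma_a(env, swim, kin, g) / gamma_r(env, swim, g))
        eta = efficiency_eta(env, swim, kin, g)
        assert eta == pytest.approx((u / (1 + u)) ** 2, rel=0.05)


class TestScalingAndSaturation:
    def test_kinase_rate_scales_as_g_squared(self, published):
        swim, kin, env = published
        gs = np.array([0.001, 0.01, 0.05]) * G_MM
        vals = [solve_kinase_filter(env, swim, kin, g).info_rate / g**2
                for g in gs]
        assert max(vals) / min(vals) < 1.02

    def test_physical_limit_g2_regime_and_saturation(self, published):
        # Idot_r/g^2 is flat deep in the shallow regime and then decreases
        # with g (the physical limit saturates)
        swim, _, env = published
        gs_flat = np.array([2e-4, 5e-4, 1e-3]) * G_MM
        flat = [solve_physical_limit_filter(env, swim, g).info_rate / g**2
                for g in gs_flat]
        assert max(flat) / min(flat) < 1.02
        gs = np.array([0.05, 0.1, 0.2, 0.3, 0.4]) * G_MM
        per_g2 = [solve_physical_limit_filter(env, swim, g).info_rate / g**2
                  for g in gs]
        assert np.all(np.diff(per_g2) < 0)

    def test_monotone_in_background_and_memory(self, published):
        swim, _, env1 = published
        g = 1e-4
        rates_r0 = [
            solve_physical_limit_filter(
                Environment(c0=c0, k_D=env1.k_D), swim, g).info_rate
            for c0 in (0.1, 1.0, 10.0)
        ]
        assert np.all(np.diff(rates_r0) > 0)
        rates_tau = [
            solve_physical_limit_filter(
                env1, replace(swim, tau_v=tv), g).info_rate
            for tv in (0.5, 1.19, 3.0)
        ]
        assert np.all(np.diff(rates_tau) > 0)

    def test_saturation_below_small_signal_extrapolation(self, published):
        swim, _, env = published
        g = 0.4 * G_MM
        i_r = solve_physical_limit_filter(env, swim, g).info_rate
        assert i_r < 0.5 * gamma_r(env, swim, g) / (4 * swim.tau_v)


class TestInfoRateFromRho:
    def test_closed_form_value(self):
        assert info_rate_from_rho(0.5, 2.0) == pytest.approx(0.5)

    def test_zero(self):
        assert info_rate_from_rho(0.0, 1.19) == 0.0

    def test_small_rho_linearization(self):
        rho2 = 1e-6
        assert info_rate_from_rho(rho2, 1.19) == pytest.approx(rho2 / 1.19,
                                                               rel=1e-5)

    def test_units_conversion(self):
        nats = info_rate_from_rho(0.3, 1.0, "nats")
        bits = info_rate_from_rho(0.3, 1.0, "bits")
        assert bits == pytest.approx(nats / np.log(2))

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            info_rate_from_rho(1.0, 1.0)


class TestEfficiency:
    def test_ideal_sensor_limit(self, published):
        swim, kin, env = published
        assert efficiency_eta(env, swim, replace(kin, D_n=1e-12),
                              2e-4) == pytest.approx(1.0, rel=0.01)

    def test_single_interior_peak_near_Ki(self, published):
        # eta(c0) at g -> 0+ rises, peaks near c0 = K_i = 0.81 uM, falls
        swim, kin, env1 = published
        c0s = np.logspace(-2, 2, 25)
        etas = []
        for c0 in c0s:
            env = Environment(c0=float(c0), k_D=env1.k_D)
            _, grkd = (kin.G_inf * c0 / (c0 + kin.K_i) / c0,) * 1 and (
                None, kin.G_inf / (c0 + kin.K_i))
            kin_c = KinasePhenotype(G_r=grkd / env.k_D, tau_2=kin.tau_2,
                                    D_n=kin.D_n, tau_n=kin.tau_n)
            etas.append(efficiency_eta(env, swim, kin_c, 0.0))
        etas = np.array(etas)
        i_pk = int(np.argmax(etas))
        assert 0 < i_pk < len(etas) - 1
        assert c0s[i_pk] == pytest.approx(0.81, rel=0.35)
        assert np.all(np.diff(etas[: i_pk + 1]) > 0)
        assert np.all(np.diff(etas[i_pk:]) < 0)

    def test_eta_rises_with_gradient(self, published):
        swim, kin, env = published
        etas = [efficiency_eta(env, swim, kin, g_mm * G_MM)
                for g_mm in (0.0, 0.1, 0.2, 0.3, 0.4)]
        assert np.all(np.diff(etas) > 0)


class TestNoisePSD:
    def test_internal_low_frequency_plateau(self, published):
        _, kin, env = published
        psd = noise_psd_components(env, kin, np.array([1e-6]))
        assert psd["internal"][0] == pytest.approx(2 * kin.D_n * kin.tau_n**2,
                                                   rel=1e-6)

    def test_internal_psd_integrates_to_variance(self, published):
        _, kin, env = published
        omega = np.linspace(0, 600.0, 4_000_001)
        psd = noise_psd_components(env, kin, omega)
        integral = 2 * np.trapezoid(psd["internal"], omega) / (2 * np.pi)
        assert integral == pytest.approx(kin.D_n * kin.tau_n, rel=1e-3)

    def test_internal_noise_dominates_observable_band(self, published):
        # at c0 = 1 uM the slow kinase noise exceeds filtered arrival noise
        # everywhere in the experimentally observable band
        _, kin, env = published
        freq = np.logspace(-3, np.log10(0.5), 100)
        psd = noise_psd_components(env, kin, 2 * np.pi * freq)
        assert np.all(psd["internal"] > psd["filtered_arrival"])


class TestBergPurcell:
    def test_shallow_gradient_fails_threshold(self, published):
        swim, _, env = published
        rep = berg_purcell_check(env, swim, 0.05 * G_MM)
        assert rep["gamma_r"] == pytest.approx(0.15, abs=0.01)
        assert not rep["passes"]

    def test_boundary_not_passing(self, published):
        swim, _, env = published
        # find g with gamma_r exactly at threshold: strict inequality fails
        g_star = np.sqrt(BERG_PURCELL_THRESHOLD /
                         (2 * env.r0 * swim.sigma_v2 * swim.tau_v**3))
        rep = berg_purcell_check(env, swim, g_star)
        assert not rep["passes"]

    def test_steep_gradient_passes(self, published):
        swim, _, env = published
        rep = berg_purcell_check(env, swim, 0.4 * G_MM)
        assert rep["gamma_r"] == pytest.approx(9.4, rel=0.02)
        assert rep["passes"]


class TestPopulationEta:
    def test_zero_spread_collapses_to_median(self, published):
        swim, kin, env = published
        out = population_eta_percentiles(env, swim, kin, cv={}, n_mc=20,
                                         seed=1)
        med = efficiency_eta(env, swim, kin, 0.0)
        for v in out["percentiles"].values():
            assert v == pytest.approx(med, rel=1e-9)

    def test_lognormal_spread_upper_tail(self, published):
        # with realistic spreads the 95th percentile sits a few-fold above
        # the median but remains far from the physical limit
        swim, kin, env = published
        cv = {"sigma_v2": 0.3, "tau_v": 0.2, "G_r": 0.4, "tau_2": 0.2,
              "D_n": 0.5, "tau_n": 0.3}
        out = population_eta_percentiles(env, swim, kin, cv=cv, n_mc=400,
                                         seed=3)
        p = out["percentiles"]
        ratio = p["p95"] / p["p50"]
        assert 2.0 < ratio < 12.0
        assert p["p95"] < 0.2

    def test_seed_reproducibility(self, published):
        swim, kin, env = published
        cv = {"G_r": 0.3, "D_n": 0.4}
        a = population_eta_percentiles(env, swim, kin, cv=cv, n_mc=50, seed=9)
        b = population_eta_percentiles(env, swim, kin, cv=cv, n_mc=50, seed=9)
        assert a["percentiles"] == b["percentiles"]
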
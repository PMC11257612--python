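"""Estimation pipeline: detection, binning, ACF fits, kernel fits, Kalman
likelihood, MWC fit, aggregation and error propagation."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from chemoinfo.estimation import (
    EnsembleSummary,
    FitResult,
    acf_covariance,
    average_step_response,
    detect_tumbles,
    estimate_fret_anchors,
    fit_exponential_acf,
    fit_mwc,
    fit_ou_noise,
    fret_to_activity,
    ou_kalman_loglik,
    population_median_uncertainty,
    propagate_uncertainty,
    prun_and_bin,
    robust_sd,
    velocity_acf,
)
from chemoinfo.models import RUN, TUMBLE, TimeSeries, Track


def _track_from_xy(t, x, y):
    return Track(t=np.asarray(t), x=np.asarray(x), y=np.asarray(y))


class TestDetectTumbles:
    def test_accuracy_on_generated_ground_truth(self, track_dataset):
        accs = []
        for tr in track_dataset[:60]:
            lab = detect_tumbles(tr)
            accs.append(np.mean(lab.state == tr.state))
        assert np.mean(accs) > 0.9

    def test_straight_track_dropped(self):
        t = np.arange(0, 20, 0.05)
        tr = _track_from_xy(t, 20 * t, np.zeros_like(t))
        lab = detect_tumbles(tr)
        assert lab.meta["n_tumbles"] == 0
        with pytest.raises(ValueError):
            prun_and_bin([lab])

    def test_stationary_cell_is_all_tumble(self):
        t = np.arange(0, 10, 0.05)
        rng = np.random.default_rng(0)
        tr = _track_from_xy(t, 0.01 * rng.standard_normal(t.size),
                            0.01 * rng.standard_normal(t.size))
        lab = detect_tumbles(tr)
        assert np.mean(lab.state == TUMBLE) > 0.95

    def test_rejects_tiny_track(self):
        with pytest.raises(ValueError):
            detect_tumbles(_track_from_xy([0, 0.05], [0, 1], [0, 0]))


class TestPrunAndBin:
    def test_identical_cells_all_selected(self, calibrated_swim, published):
        from chemoinfo.models import Environment
        from chemoinfo.synthetic import PopulationSpec, generate_track_dataset

        _, kin, env = published
        pop = PopulationSpec(swim=calibrated_swim, kin=kin, n_cells=20, cv={})
        tracks = generate_track_dataset(
            pop, Environment(c0=1.0, g=0.0, k_D=env.k_D), 60.0, 0.05, seed=1)
        labeled = [detect_tumbles(tr) for tr in tracks]
        subset, pruns = prun_and_bin(labeled, window=1.0)
        assert len(subset) == len(labeled)

    def test_all_run_cell_has_unit_prun(self):
        t = np.arange(0, 20, 0.05)
        tr = Track(t=t, x=20 * t, y=np.zeros_like(t),
                   state=np.full(t.size, RUN, dtype=np.int8),
                   meta={"n_tumbles": 2})
        subset, pruns = prun_and_bin([tr, tr])
        assert pruns[0] == 1.0

    def test_window_widening_warns(self):
        t = np.arange(0, 20, 0.05)
        trs = []
        for p, ntum in ((0.2, 2), (0.9, 2), (0.5, 2)):
            state = np.where(np.arange(t.size) < p * t.size, RUN, TUMBLE)
            trs.append(Track(t=t, x=20 * t, y=np.zeros_like(t),
                             state=state.astype(np.int8),
                             meta={"n_tumbles": ntum}))
        # median is isolated: +-0.01 bin contains it, so no widening needed
        subset, _ = prun_and_bin(trs)
        assert len(subset) == 1

    def test_bin_occupancy_matches_population_spread(self, track_dataset):
        labeled = [detect_tumbles(tr) for tr in track_dataset]
        subset, pruns = prun_and_bin(labeled)
        # binomial count of cells within +-0.01 of the median
        med = np.median(pruns)
        p_hit = np.mean(np.abs(pruns - med) <= 0.01)
        n = len(pruns)
        se = np.sqrt(p_hit * (1 - p_hit) * n)
        assert abs(len(subset) - p_hit * n) <= 3 * se + 1


class TestVelocityACF:
    def test_white_noise_velocity_has_no_correlation(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 60, 0.05)
        x = np.cumsum(rng.standard_normal(t.size)) * 0.05 * 10
        tr = _track_from_xy(t, x, np.zeros_like(t))
        lags, V, se = velocity_acf([tr], max_lag_s=2.0)
        assert np.all(np.abs(V[5:]) < 5 * np.abs(V[0]) / np.sqrt(t.size / 5))

    def test_duration_weighting(self):
        rng = np.random.default_rng(2)
        mk = lambda T, amp: _track_from_xy(
            np.arange(0, T, 0.05),
            np.cumsum(amp * np.ones(int(T / 0.05))) * 0.05,
            np.zeros(int(T / 0.05)))
        short = mk(10.0, 5.0)   # V(0) = 25
        long = mk(1000.0, 20.0)  # V(0) = 400
        lags, V, _ = velocity_acf([short, long], max_lag_s=1.0)
        w1, w2 = short.duration, long.duration
        expect = (w1 * 25 + w2 * 400) / (w1 + w2)
        assert V[0] == pytest.approx(expect, rel=1e-9)
        assert abs(V[0] - 400) / 400 < 0.02  # dominated by the long cell

    def test_lag_grid_truncation_warns(self):
        t = np.arange(0, 5, 0.05)
        tr = _track_from_xy(t, 20 * t, np.zeros_like(t))
        with pytest.warns(UserWarning, match="truncated"):
            velocity_acf([tr], max_lag_s=10.0)


class TestFitExponentialACF:
    def test_noiseless_identifiability(self):
        lags = np.arange(0, 10.01, 0.05)
        V = 146.0 * np.exp(-lags / 1.19)
        se = np.full(lags.size, 1e-6)
        fit = fit_exponential_acf(lags, V, se, seed=0, n_steps=400)
        assert fit.map_estimate["sigma_v2"] == pytest.approx(146.0, rel=1e-5)
        assert fit.map_estimate["tau_v"] == pytest.approx(1.19, rel=1e-5)

    def test_fit_range_excludes_origin(self):
        lags = np.arange(0, 10.01, 0.05)
        V = 100.0 * np.exp(-lags / 1.0)
        V[0] = 1e6  # a corrupted lag-0 point must not affect the fit
        se = np.full(lags.size, 1e-3)
        fit = fit_exponential_acf(lags, V, se, seed=0, n_steps=400)
        assert fit.map_estimate["sigma_v2"] == pytest.approx(100.0, rel=1e-3)

    def test_bartlett_covariance_is_positive_definite(self):
        lags = np.arange(0.1, 10.01, 0.05)
        C = acf_covariance(lags, 146.0, 1.19, 6000.0)
        w = np.linalg.eigvalsh(C)
        assert w.min() > -1e-10 * w.max()


class TestAverageStepResponse:
    def _blocks(self, n_rep, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 37.5, 0.75)
        blocks = []
        for i in range(2 * n_rep):
            direction = "up" if i % 2 == 0 else "down"
            sign = -1.0 if direction == "up" else 1.0
            resp = np.where(t >= 7.5, sign * 0.2 * np.exp(-(t - 7.5) / 7.4),
                            0.0)
            vals = 0.3 + resp + noise * rng.standard_normal(t.size)
            blocks.append(TimeSeries(t=t, values=vals, meta={
                "direction": direction, "step_onset_s": 7.5,
                "delta_c": 0.08 if direction == "up" else -0.08}))
        return blocks

    def test_identical_repeats_have_zero_sem(self):
        avg = average_step_response(self._blocks(3))
        assert np.allclose(avg["up"]["sem"], 0.0)

    def test_antisymmetric_directions(self):
        avg = average_step_response(self._blocks(4))
        assert np.allclose(avg["up"]["mean"], -avg["down"]["mean"], atol=1e-12)

    def test_single_repeat_flagged(self):
        blocks = self._blocks(1)
        avg = average_step_response(blocks[:1])
        assert not avg["up"]["ok"]


class TestFitOuNoise:
    def test_kalman_equals_dense_gaussian(self):
        # small-instance oracle: scalar Kalman vs full covariance logpdf
        rng = np.random.default_rng(3)
        n, dt, Dn, taun, a0, sm = 100, 1.0, 8.1e-4, 8.7, 0.3, 0.02
        y = a0 + 0.05 * rng.standard_normal(n)
        t = np.arange(n) * dt
        C = Dn * taun * np.exp(-np.abs(t[:, None] - t[None, :]) / taun)
        C += sm**2 * np.eye(n)
        ll_dense = multivariate_normal.logpdf(y, mean=np.full(n, a0), cov=C)
        ll_kalman = ou_kalman_loglik(y, dt, Dn, taun, a0, sm)
        assert ll_kalman == pytest.approx(ll_dense, abs=1e-8)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(4)
        y = 0.3 + 0.05 * rng.standard_normal(300)
        f = ou_kalman_loglik(y, 1.0, 8e-4, 8.0, 0.3, 0.02)
        b = ou_kalman_loglik(y[::-1].copy(), 1.0, 8e-4, 8.0, 0.3, 0.02)
        assert f == pytest.approx(b, abs=1e-7)

    def test_zero_diffusivity_generator_flagged(self):
        rng = np.random.default_rng(5)
        tr = TimeSeries(t=np.arange(600.0),
                        values=0.3 + 0.02 * rng.standard_normal(600))
        fit = fit_ou_noise(tr, 0.02, seed=0, n_steps=400)
        assert (fit.diagnostics.get("at_lower_prior_edge")
                or fit.map_estimate["D_n"] * fit.map_estimate["tau_n"] < 1e-4)

    def test_recovery_on_single_long_trace(self, published):
        from chemoinfo.synthetic import PopulationSpec, generate_noise_dataset

        swim, kin, env = published
        pop = PopulationSpec(swim=swim, kin=kin, n_cells=1, cv={},
                             measurement_noise_sd=0.02)
        tr = generate_noise_dataset(pop, env, duration_s=6000.0, seed=6)[0]
        fit = fit_ou_noise(tr, 0.02, seed=0, n_steps=400)
        assert fit.map_estimate["D_n"] == pytest.approx(
            kin.D_n, abs=3 * fit.uncertainty["D_n"])
        assert fit.map_estimate["tau_n"] == pytest.approx(
            kin.tau_n, abs=3 * fit.uncertainty["tau_n"])


class TestFitMwc:
    def test_exact_model_recovery(self):
        c0s = [0.1, 1.0, 10.0]
        table = [(c, 3.5 / (c + 0.81), 0.05) for c in c0s]
        out = fit_mwc(table)
        assert out["G_inf"] == pytest.approx(3.5, rel=1e-6)
        assert out["K_i"] == pytest.approx(0.81, rel=1e-6)

    def test_printed_gain_triples(self):
        out = fit_mwc([(0.1, 3.2, 0.1), (1.0, 2.28, 0.05),
                       (10.0, 0.251, 0.009)])
        assert out["G_inf"] == pytest.approx(3.5, abs=0.1)
        assert out["K_i"] == pytest.approx(0.81, abs=0.04)

    def test_objective_weighting_audit(self):
        # asymmetric errors: the weighted objective shifts the fit toward
        # the precise point, the unweighted one does not
        table_tight_low = [(0.1, 3.5 / 0.91, 1e-4),
                           (1.0, 1.6, 0.5),
                           (10.0, 3.5 / 10.81 * 10 / 10, 0.5)]
        table = [(0.1, 3.5 / 0.91, 1e-4), (1.0, 1.6, 0.5), (10.0, 0.32, 0.5)]
        w = fit_mwc(table, weighted=True)
        u = fit_mwc(table, weighted=False)
        # weighted fit honors the tight point almost exactly
        pred_w = w["G_inf"] * 0.1 / (0.1 + w["K_i"]) / 0.1
        assert pred_w == pytest.approx(3.5 / 0.91, rel=0.01)
        assert w["G_inf"] != pytest.approx(u["G_inf"], rel=1e-3)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_mwc([(1.0, 2.0, 0.1)])
        with pytest.raises(ValueError):
            fit_mwc([(1.0, -2.0, 0.1), (10.0, 1.0, 0.1)])


class TestAggregation:
    def _fit(self, map_val, sigma):
        samples = np.full((10, 1), map_val)
        return FitResult(param_names=["x"], map_estimate={"x": map_val},
                         samples=samples, uncertainty={"x": sigma})

    def test_hand_computed_fixture(self):
        # N=2, MAPs {1,3}, per-cell sigma^2 {0.04, 0.09}
        fits = [self._fit(1.0, 0.2), self._fit(3.0, 0.3)]
        out = population_median_uncertainty(fits, "x")
        term1 = (1.4826 * 1.0) ** 2 / 2
        term2 = (0.04 + 0.09) / 4
        assert out.median == pytest.approx(2.0)
        assert out.sem2 == pytest.approx(term1 + term2, rel=1e-12)

    def test_zero_spread_zero_uncertainty(self):
        fits = [self._fit(2.0, 0.0) for _ in range(5)]
        out = population_median_uncertainty(fits, "x")
        assert out.sem2 == 0.0

    def test_terms_scale_with_cell_count(self):
        rng = np.random.default_rng(7)
        maps = rng.normal(5.0, 1.0, 64)
        for N in (16, 64):
            fits = [self._fit(m, 0.0) for m in maps[:N]]
            out_spread = population_median_uncertainty(fits, "x")
            fits_u = [self._fit(5.0, 0.5) for _ in range(N)]
            out_unc = population_median_uncertainty(fits_u, "x")
            # first term ~ 1/N, second term ~ 1/N
            assert out_unc.sem2 == pytest.approx(N * 0.25 / N**2, rel=1e-9)
        # cell-to-cell term halves (in sd) from N=16 to N=64

    def test_mad_estimates_gaussian_sd(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 2.5, 100_000)
        assert robust_sd(x) == pytest.approx(2.5, rel=0.02)


class TestPropagateUncertainty:
    def test_linear_function_exact(self):
        f = lambda a, b: 2 * a - 3 * b
        sig = propagate_uncertainty(f, {"a": 1.0, "b": 2.0},
                                    {"a": 0.1, "b": 0.2})
        assert sig == pytest.approx(np.sqrt(0.04 + 0.36), rel=1e-6)

    def test_product_adds_relative_variances(self):
        f = lambda a, b: a * b
        sig = propagate_uncertainty(f, {"a": 3.0, "b": 4.0},
                                    {"a": 0.3, "b": 0.2})
        expect = 12.0 * np.sqrt((0.1) ** 2 + (0.05) ** 2)
        assert sig == pytest.approx(expect, rel=1e-4)

    def test_eta_uncertainty_scale(self, published):
        # propagated through the full filter ratio, the printed parameter
        # uncertainties give a shallow-limit eta error of order 1e-3
        from chemoinfo.information import efficiency_eta
        from chemoinfo.models import Environment, KinasePhenotype, SwimmingPhenotype

        swim, kin, env = published

        def eta_of(sigma_v2, tau_v, G_r_kD, tau_2, D_n, tau_n):
            sw = replace(swim, sigma_v2=sigma_v2, tau_v=tau_v)
            kn = KinasePhenotype(G_r=G_r_kD / env.k_D, tau_2=tau_2, D_n=D_n,
                                 tau_n=tau_n)
            return efficiency_eta(env, sw, kn, 0.0)

        theta = {"sigma_v2": 146.0, "tau_v": 1.19, "G_r_kD": 2.28,
                 "tau_2": 7.4, "D_n": 8.1e-4, "tau_n": 8.7}
        sigma = {"sigma_v2": 5.0, "tau_v": 0.01, "G_r_kD": 0.05,
                 "tau_2": 0.3, "D_n": 0.9e-4, "tau_n": 0.9}
        sig_eta = propagate_uncertainty(eta_of, theta, sigma)
        assert 5e-4 < sig_eta < 5e-3  # printed +-0.002 scale


class TestFretNormalization:
    def _trace(self, vals):
        return TimeSeries(t=np.arange(len(vals), dtype=float),
                          values=np.asarray(vals, dtype=float))

    def test_anchors_map_to_unit_interval(self):
        tr = self._trace([0.1, 0.5, 0.9])
        a = fret_to_activity(tr, 0.1, 0.9)
        assert a.values[0] == 0.0 and a.values[-1] == 1.0

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=-5.0, max_value=5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        tr = self._trace([0.2, 0.4, 0.7, 1.1])
        a1 = fret_to_activity(tr, 0.2, 1.1).values
        tr2 = self._trace(scale * tr.values + shift)
        a2 = fret_to_activity(tr2, scale * 0.2 + shift,
                              scale * 1.1 + shift).values
        assert np.allclose(a1, a2, atol=1e-12)

    def test_rejects_degenerate_anchors(self):
        with pytest.raises(ValueError):
            fret_to_activity(self._trace([1, 2, 3.0]), 1.0, 1.0)

    def test_anchor_estimation_windows(self):
        sat = self._trace(np.full(20, 0.15))
        removal = self._trace(np.linspace(0.9, 0.5, 20))
        fmin, fmax = estimate_fret_anchors(sat, removal, removal_window_s=2.5)
        assert fmin == pytest.approx(0.15)
        # mean over the first 2.5 s (samples at t=0,1,2)
        assert fmax == pytest.approx(np.mean(removal.values[:3]))
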
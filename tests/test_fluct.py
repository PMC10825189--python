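"""Autocorrelation analysis: estimator identities, fits, ensemble behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trace
from dnadevice.fluct import (
    FluctuationModel,
    LogisticLengthModel,
    compute_acf,
    fit_logistic_counts,
    fit_monoexponential,
    ideal_acf,
    linear_drift,
    median_acf,
    spot_accounting,
)
from dnadevice.simkit import SimConfig, simulate_ensemble


class TestComputeACF:
    def test_alternating_trace_hand_computed(self):
        # [2,0,2,0,2,0]: mu=1, per-lag pair-count estimator gives
        # G(0)=1 and G(1 lag)=-1 by direct pairwise sums
        acf = compute_acf(make_trace([2, 0, 2, 0, 2, 0]))
        assert acf.mean == pytest.approx(1.0)
        assert acf.g[0] == pytest.approx(1.0)
        assert acf.g[1] == pytest.approx(-1.0)

    def test_g0_equals_moment_identity(self, rng):
        # G(0) = sigma^2/mu^2 exactly, same estimator on both sides
        x = rng.lognormal(1.0, 0.5, size=200)
        acf = compute_acf(make_trace(x))
        assert acf.g[0] == pytest.approx(np.var(x) / np.mean(x) ** 2, rel=1e-12)

    def test_iid_noise_decorrelates(self, rng):
        n = 20_000
        x = 10.0 + rng.normal(0, 1, size=n)
        acf = compute_acf(make_trace(x), max_lag=200.0)
        assert np.all(np.abs(acf.g[1:] / acf.g[0]) < 3 / math.sqrt(n))

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        g1 = compute_acf(make_trace(x)).g
        g2 = compute_acf(make_trace(c * x)).g
        np.testing.assert_allclose(g1, g2, rtol=1e-9)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_acf(make_trace([5, 5, 5, 5, 5]))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_acf(make_trace([1, 2, 3]))


class TestMedianACF:
    def test_single_is_identity(self):
        a = compute_acf(make_trace([2, 0, 2, 0, 2, 0]))
        m = median_acf([a])
        np.testing.assert_array_equal(m.g, a.g)

    def test_median_of_three(self):
        acfs = []
        for scale, seq in [(1, [1, 2, 1, 3]), (1, [4, 1, 2, 2]), (1, [9, 2, 2, 1])]:
            acfs.append(compute_acf(make_trace(seq)))
        m = median_acf(acfs)
        stacked = np.stack([a.g for a in acfs])
        np.testing.assert_allclose(m.g, np.median(stacked, axis=0))

    def test_mismatched_grids_rejected(self):
        a = compute_acf(make_trace([1, 2, 1, 3, 2, 1]))
        b = compute_acf(make_trace([1, 2, 1, 3]))
        with pytest.raises(ValueError, match="common delay grid"):
            median_acf([a, b])


class TestMonoExponentialFit:
    def test_recovers_exact_exponential(self):
        tau = np.arange(0, 600, 4.0)
        g = 0.5 * np.exp(-tau / 120.0)
        from dnadevice.fluct import ACFResult
        res = fit_monoexponential(ACFResult(tau=tau, g=g, mean=1.0, std=1.0))
        assert res.g0_inverse == pytest.approx(2.0, rel=1e-6)
        assert res.tau_c == pytest.approx(120.0, rel=1e-6)

    def test_bleaching_bounds_correlation_time(self):
        # random single-protein birth with 90 s bleaching: fitted tau_C
        # stays below the bleaching time for every extension length
        for dl, seed in [(862, 21), (1500, 22), (1980, 23)]:
            cfg = SimConfig(gene_extension_length=dl, initiation_rate=0.01,
                            bleach_time=90.0, duration=3600, seed=seed)
            res = FluctuationModel.from_simulation(cfg, 150).fit(n_boot=30, seed=1)
            assert res.tau_c <= 90.0 + 3 * res.tau_c_se

    def test_bursting_extends_correlation_time(self):
        # correlated production lengthens the apparent correlation time
        # relative to random birth at matched conditions (same seed protocol)
        base = dict(gene_extension_length=1980, initiation_rate=0.005,
                    bleach_time=90.0, duration=3600)
        r_rand = FluctuationModel.from_simulation(
            SimConfig(**base, seed=31), 200, mode="random").fit(n_boot=30, seed=2)
        r_burst = FluctuationModel.from_simulation(
            SimConfig(**base, burst_mean_size=3.0, burst_spacing=30.0, seed=31),
            200, mode="burst").fit(n_boot=30, seed=2)
        se = math.hypot(r_rand.tau_c_se, r_burst.tau_c_se)
        assert r_burst.tau_c > r_rand.tau_c + 3 * se


class TestIdealACF:
    def test_closed_form_values(self):
        assert ideal_acf(0.01, 112.0, 0.0) == pytest.approx(1 / (0.01 * 112.0))
        assert ideal_acf(0.01, 112.0, 112.0) == 0.0
        assert ideal_acf(0.01, 112.0, 200.0) == 0.0
        assert ideal_acf(0.01, 112.0, 56.0) == pytest.approx(1 / (2 * 0.01 * 112.0))

    def test_ensemble_acf_matches_triangle_without_bleaching(self, no_bleach_config):
        # bleach-free random birth: median ACF converges to the triangular
        # closed form with T the visible window (residence minus folding)
        traces = simulate_ensemble(no_bleach_config, 250)
        model = FluctuationModel(traces, max_lag=240.0)
        res = model.fit(n_boot=40, seed=3)
        T_vis = 198.0 - 86.0
        k = no_bleach_config.initiation_rate
        acfs = np.stack([a.g for a in res.spot_acfs])
        med = np.median(acfs, axis=0)
        se = 1.2533 * np.std(acfs, axis=0, ddof=1) / math.sqrt(len(traces))
        ideal = ideal_acf(k, T_vis, res.median.tau)
        # compare away from the smoothed cutoff at tau ~ T_vis
        mask = res.median.tau < 0.8 * T_vis
        assert np.all(np.abs(med[mask] - ideal[mask]) < 5 * se[mask] + 0.02 * ideal[0])

    def test_parameter_recovery_from_triangle(self, no_bleach_config):
        # planted (k_tx, T) recoverable from G(0)^-1 = k T and the tau-intercept
        traces = simulate_ensemble(no_bleach_config, 500)
        res = FluctuationModel(traces, max_lag=240.0).fit()
        med = res.median
        T_vis = 198.0 - 86.0
        # linear fit over the triangular part: G = G0 (1 - tau/T)
        mask = med.tau < 0.7 * T_vis
        slope, intercept = np.polyfit(med.tau[mask], med.g[mask], 1)
        T_hat = -intercept / slope
        k_hat = 1.0 / (intercept * T_hat)
        assert T_hat == pytest.approx(T_vis, rel=0.10)
        assert k_hat == pytest.approx(no_bleach_config.initiation_rate, rel=0.10)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            ideal_acf(0.0, 100.0, 1.0)


class TestLinearDrift:
    def test_exact_line(self):
        tr = make_trace(2.0 * np.arange(10) * 4.0 + 1.0)
        D, b = linear_drift(tr)
        assert D == pytest.approx(2.0)
        assert b == pytest.approx(1.0)

    def test_constant_trace(self):
        D, _ = linear_drift(make_trace([3.0] * 8))
        assert D == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovery(self, rng):
        n = 450
        t = np.arange(n) * 4.0
        sigma = 5.0
        tr = make_trace(0.05 * t + rng.normal(0, sigma, n))
        D, _ = linear_drift(tr)
        se = sigma / math.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(D - 0.05) < 3 * se


class TestLogisticFit:
    def test_self_consistency(self):
        L = np.array([400, 600, 800, 862, 1000, 1300, 1800, 2200], float)
        y = 5.0 + (100.0 - 5.0) / (1 + np.exp(-(L - 862.0) / 80.0))
        fit = fit_logistic_counts(L, y)
        assert fit.midpoint == pytest.approx(862.0, abs=1e-3)
        assert fit.plateau == pytest.approx(100.0, rel=1e-4)

    def test_decreasing_counts_flagged(self):
        L = [400, 800, 1200, 1600, 2000]
        y = [100, 80, 50, 20, 5]
        with pytest.raises(RuntimeError, match="decreasing"):
            fit_logistic_counts(L, y)

    def test_midpoint_from_mechanistic_sweep(self):
        # detection probabilities from the folding/release model yield a
        # logistic midpoint at the length where residence equals folding time
        base = SimConfig(gene_extension_length=1, initiation_rate=0.01, seed=41)
        model = LogisticLengthModel.from_detection_sweep(
            base, [531, 730, 862, 1100, 1500, 1980], n_reps=10_000)
        fit = model.fit()
        assert fit.midpoint == pytest.approx(860.0, abs=15.0)


class TestSpotAccounting:
    def test_study_counts(self):
        specific, unidentified = spot_accounting(131, 1123, 0.30)
        assert specific == pytest.approx((1123 - 131) / 1123)
        assert specific == pytest.approx(0.88, abs=0.005)
        assert unidentified == pytest.approx(0.58, abs=0.005)

    def test_no_nonspecific_spots(self):
        specific, unidentified = spot_accounting(0, 500, 0.0)
        assert specific == 1.0
        assert unidentified == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            spot_accounting(600, 500)
        with pytest.raises(ValueError):
            spot_accounting(131, 1123, 0.95)


class TestFluctuationModelInterface:
    def test_summary_reports_fit(self, bleach_config):
        res = FluctuationModel.from_simulation(bleach_config, 30).fit()
        text = res.summary()
        assert "tau_C" in text and "G(0)^-1" in text
        assert res.to_frame().shape[1] == 2
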
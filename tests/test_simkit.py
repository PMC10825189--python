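"""Simulator: event model, occupancy bookkeeping, detection, movie rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dnadevice.simkit import (
    IntensityTrace,
    MovieSpec,
    ProteinEvent,
    SimConfig,
    detection_probability,
    occupancy,
    render_movie,
    sample_burst_on_times,
    simulate_trace,
)


class TestSimConfig:
    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            SimConfig(gene_extension_length=-1, initiation_rate=0.01)
        with pytest.raises(ValueError):
            SimConfig(gene_extension_length=100, initiation_rate=float("nan"))
        with pytest.raises(ValueError):
            SimConfig(gene_extension_length=100, initiation_rate=0.01, burst_mean_size=0.5)
        with pytest.raises(ValueError):
            SimConfig(gene_extension_length=100, initiation_rate=0.01, dt=0)

    def test_derived_times(self):
        cfg = SimConfig(gene_extension_length=1980, initiation_rate=0.01,
                        dye_binding_time=2.0)
        assert cfg.residence_time == pytest.approx(198.0)
        assert cfg.maturation_delay == pytest.approx(88.0)

    def test_protein_event_ordering_enforced(self):
        with pytest.raises(ValueError):
            ProteinEvent(t_init=10.0, t_fluoresce=5.0, t_release=20.0, t_bleach=math.inf)


class TestSimulateTrace:
    def test_release_before_folding_gives_pure_noise(self):
        # deterministic residence (cv=0) well below the folding delay:
        # no protein ever fluoresces on the DNA
        cfg = SimConfig(gene_extension_length=500, initiation_rate=0.05,
                        residence_cv=0.0, noise_sigma=0.5, duration=2000, seed=1)
        trace, events = simulate_trace(cfg, "random")
        assert len(events) > 0
        assert all(not np.isfinite(ev.t_fluoresce) for ev in events)
        assert abs(float(np.mean(trace.intensity))) < 5 * 0.5 / math.sqrt(len(trace))

    def test_zero_rate_gives_noise_only(self):
        cfg = SimConfig(gene_extension_length=1980, initiation_rate=0.0,
                        noise_sigma=1.0, duration=400, seed=2)
        trace, events = simulate_trace(cfg, "random")
        assert events == []
        assert np.std(trace.intensity) > 0

    def test_littles_law_occupancy(self):
        # long-run mean fluorescent-tethered count = k_tx * (T - t_fold)
        # when bleaching is off and T >> residence spread
        cfg = SimConfig(gene_extension_length=1980, initiation_rate=0.01,
                        bleach_time=float("inf"), duration=200_000, seed=3)
        trace, events = simulate_trace(cfg, "random")
        expected = 0.01 * (198.0 - 86.0)
        assert float(np.mean(trace.intensity)) == pytest.approx(expected, rel=0.05)

    def test_trace_mean_equals_event_list_occupancy(self, bleach_config):
        # exact noise-free identity between the trace and its ground truth
        trace, events = simulate_trace(bleach_config, "random")
        assert bleach_config.noise_sigma == 0
        np.testing.assert_allclose(trace.intensity, occupancy(events, trace.t))

    @pytest.mark.parametrize("mode", ["random", "burst"])
    def test_bit_reproducible_under_seed(self, mode):
        cfg = SimConfig(gene_extension_length=1980, initiation_rate=0.02,
                        burst_mean_size=3.0, noise_sigma=0.3, duration=1000, seed=9)
        t1, e1 = simulate_trace(cfg, mode)
        t2, e2 = simulate_trace(cfg, mode)
        np.testing.assert_array_equal(t1.intensity, t2.intensity)
        assert e1 == e2

    def test_burst_mode_produces_clustered_initiations(self):
        cfg = SimConfig(gene_extension_length=1980, initiation_rate=0.002,
                        burst_mean_size=4.0, burst_spacing=20.0, duration=50_000, seed=4)
        _, ev_burst = simulate_trace(cfg, "burst")
        _, ev_rand = simulate_trace(cfg.replace(seed=5), "random")
        # bursts multiply the event count by roughly the mean burst size
        assert len(ev_burst) > 2 * len(ev_rand)
        gaps = np.diff([e.t_init for e in ev_burst])
        # short within-burst gaps dominate relative to a Poisson process
        assert np.median(gaps) < 1.0 / cfg.initiation_rate / 4


class TestDetectionProbability:
    def test_zero_extension(self):
        cfg = SimConfig(gene_extension_length=0, initiation_rate=0.01, seed=0)
        assert detection_probability(cfg, 100) == 0.0

    def test_threshold_length_is_half(self):
        # residence symmetric about the maturation delay: exactly half detected
        cfg = SimConfig(gene_extension_length=860, initiation_rate=0.01, seed=1)
        p = detection_probability(cfg, 200_000)
        assert p == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(200_000))

    def test_monte_carlo_matches_normal_tail(self):
        cfg = SimConfig(gene_extension_length=1100, initiation_rate=0.01, seed=2)
        n = 100_000
        p_mc = detection_probability(cfg, n)
        T = cfg.residence_time
        p_exact = float(norm.sf(86.0, loc=T, scale=0.1 * T))
        se = math.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(p_mc - p_exact) < 3 * se
        assert detection_probability(cfg, 1, method="analytic") == pytest.approx(p_exact)

    def test_rejects_bad_reps(self):
        cfg = SimConfig(gene_extension_length=860, initiation_rate=0.01)
        with pytest.raises(ValueError):
            detection_probability(cfg, 0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=40))
    def test_nondecreasing_in_length(self, step):
        # analytic form is monotone; Monte-Carlo version tracks it within noise
        la, lb = 400 + 40 * step, 440 + 40 * step
        pa = detection_probability(
            SimConfig(gene_extension_length=la, initiation_rate=0.01), 1, method="analytic")
        pb = detection_probability(
            SimConfig(gene_extension_length=lb, initiation_rate=0.01), 1, method="analytic")
        assert pb >= pa
        assert 0.0 <= pa <= 1.0


class TestBurstOnTimes:
    def test_mean_on_time_matches_closed_form(self):
        cfg = SimConfig(gene_extension_length=1980, initiation_rate=0.01,
                        burst_mean_size=3.0, burst_spacing=30.0, seed=6)
        times = sample_burst_on_times(cfg, 20_000)
        expected = (3.0 - 1.0) * 30.0 + 198.0
        se = float(np.std(times, ddof=1) / math.sqrt(len(times)))
        assert abs(float(np.mean(times)) - expected) < 3 * se


class TestRenderMovie:
    def test_empty_spec_is_background_noise(self):
        spec = MovieSpec(n_frames=3, shape=(32, 32), background=50.0,
                         noise_sigma=1.0, seed=0)
        stacks, truth = render_movie(spec)
        assert truth.empty
        for ch in (0, 1):
            assert stacks[ch].shape == (3, 32, 32)
            assert float(np.mean(stacks[ch])) == pytest.approx(50.0, abs=0.5)

    def test_static_bead_gives_identical_frames(self):
        spec = MovieSpec(n_frames=4, shape=(32, 32),
                         bead_positions=np.array([[16.0, 16.0]]), noise_sigma=0.0)
        stacks, truth = render_movie(spec)
        for ch in (0, 1):
            for f in range(1, 4):
                np.testing.assert_array_equal(stacks[ch][f], stacks[ch][0])
        assert set(truth["kind"]) == {"bead"}

    def test_linear_drift_displaces_bead(self):
        n = 100
        drift = np.stack([np.zeros(n), 0.1 * np.arange(n)], axis=1)
        spec = MovieSpec(n_frames=n, shape=(48, 48),
                         bead_positions=np.array([[24.0, 10.0]]),
                         drift=drift, noise_sigma=0.0)
        stacks, truth = render_movie(spec)
        bead = truth[(truth.kind == "bead") & (truth.channel == 1)]
        assert bead.iloc[-1].x_px - bead.iloc[0].x_px == pytest.approx(9.9)
        # intensity-weighted centroid moved by the same amount
        def centroid_col(img):
            cc = np.arange(img.shape[1])
            w = img - img.min()
            return float((w.sum(axis=0) * cc).sum() / w.sum())
        shift = centroid_col(stacks[1][-1]) - centroid_col(stacks[1][0])
        assert shift == pytest.approx(9.9, abs=0.05)

    def test_out_of_bounds_drift_warns(self):
        drift = np.stack([np.zeros(5), np.arange(5) * 10.0], axis=1)
        spec = MovieSpec(n_frames=5, shape=(16, 16),
                         bead_positions=np.array([[8.0, 8.0]]), drift=drift)
        with pytest.warns(UserWarning, match="drifted outside"):
            render_movie(spec)

    def test_positions_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            MovieSpec(n_frames=2, shape=(16, 16),
                      bead_positions=np.array([[20.0, 8.0]]))

    def test_reproducible_under_seed(self):
        spec = dict(n_frames=3, shape=(24, 24), noise_sigma=2.0, seed=5,
                    bead_positions=np.array([[12.0, 12.0]]))
        s1, _ = render_movie(MovieSpec(**spec))
        s2, _ = render_movie(MovieSpec(**spec))
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])
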
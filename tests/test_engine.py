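"""Trial simulation: stimulus mapping, alpha modulation, scheduling, determinism."""

import math

import numpy as np
import pytest

from satnet import (
    AlphaModulation,
    NetworkConfig,
    StimulusDrive,
    TrialProtocol,
    map_stimulus,
    run_trial,
    sample_input_counts,
    theta_at,
)
from satnet.engine import draw_event_stream, draw_window_counts


class TestThetaAt:
    def test_zero_amplitude_is_identity(self):
        mod = AlphaModulation(amplitude=0.0)
        for t in (0.0, 13.0, 997.5):
            assert theta_at(t, mod) == 0.13
        assert theta_at(50.0, None) == 0.13

    def test_full_amplitude_swings_between_printed_extremes(self):
        mod = AlphaModulation(amplitude=0.1, frequency_hz=10.0, phase=0.0)
        t = np.linspace(0, 200, 200001)
        vals = 0.13 + mod.amplitude * np.sin(mod.omega * t + mod.phase)
        assert vals.min() == pytest.approx(0.03, abs=1e-6)
        assert vals.max() == pytest.approx(0.23, abs=1e-6)

    def test_trough_value_at_quarter_period(self):
        mod = AlphaModulation(amplitude=0.05, frequency_hz=10.0, phase=0.0)
        t_trough = 75.0  # sin(2*pi*10*t/1000) = -1 at t = 75 ms
        assert theta_at(t_trough, mod) == pytest.approx(0.08, abs=1e-12)

    def test_amplitude_domain(self):
        with pytest.raises(ValueError, match="amplitude"):
            AlphaModulation(amplitude=0.2)


class TestMapStimulus:
    def test_symmetric_zero_evidence(self):
        assert map_stimulus("coherence", 0.0) == (7.5, 7.5)

    def test_contrast_mapping(self):
        la, lb = map_stimulus("contrast", 0.0498)
        assert la == pytest.approx(8.247)
        assert lb == pytest.approx(6.753)

    def test_coherence_mapping(self):
        la, lb = map_stimulus("coherence", 0.512)
        assert la == pytest.approx(11.34)
        assert lb == pytest.approx(3.66)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            map_stimulus("contrast", 0.6)
        with pytest.raises(ValueError):
            StimulusDrive(mode="contrast", c=-0.1)


class TestInputCounts:
    def test_zero_rate_never_counts(self, rng):
        drive = StimulusDrive(mode="raw", lambda_A=0.0, lambda_B=0.0)
        for w in range(5):
            assert sample_input_counts(drive, w, rng) == (0.0, 0.0)

    def test_poisson_mean(self, rng):
        drive = StimulusDrive(mode="raw", lambda_A=9.0, lambda_B=9.0)
        draws = np.array([sample_input_counts(drive, w, rng)[0] for w in range(2000)])
        se = math.sqrt(9.0 / 2000)
        assert abs(draws.mean() - 9.0) < 3 * se

    def test_constant_style_returns_means(self, rng):
        drive = StimulusDrive(mode="coherence", c=0.512, input_style="constant")
        assert sample_input_counts(drive, 0, rng) == (11.34, 3.66)

    def test_one_draw_per_window_cadence(self, rng):
        drive = StimulusDrive(mode="coherence", c=0.1)
        ca, cb = draw_window_counts(rng, drive, 2000.0)
        assert len(ca) == len(cb) == math.ceil(2000 / 30)


class TestEventStream:
    def test_mean_interval_matches_per_neuron_rate(self, rng):
        cfg = NetworkConfig()
        times, neurons = draw_event_stream(rng, 1000.0, cfg.tau2, cfg.N)
        intervals = np.diff(times)
        expected = 1.0 / (cfg.N * cfg.tau2)
        assert intervals.mean() == pytest.approx(expected, rel=0.05)
        assert times[-1] >= 1000.0
        assert neurons.min() >= 0 and neurons.max() < cfg.N


class TestRunTrial:
    def test_identical_seeds_identical_spike_logs(self, tiny_config):
        proto = TrialProtocol(pre_ms=100, max_decision_ms=400, decision_threshold_hz=50)
        drive = StimulusDrive(mode="contrast", c=0.1, lambda0=4.0)
        r1 = run_trial(tiny_config, drive, None, proto, rng=99)
        r2 = run_trial(tiny_config, drive, None, proto, rng=99)
        assert np.array_equal(r1.spike_log[0], r2.spike_log[0])
        assert np.array_equal(r1.spike_log[1], r2.spike_log[1])
        assert r1.choice == r2.choice and r1.rt_ms == r2.rt_ms

    def test_refractory_floor_on_interspike_intervals(self, default_config):
        proto = TrialProtocol(pre_ms=0, max_decision_ms=1500, decision_threshold_hz=1e9)
        r = run_trial(default_config, None, None, proto, rng=5, detect=False)
        times, neurons = r.spike_log
        R = default_config.refractory_ms
        for j in np.unique(neurons[:2000]):
            isi = np.diff(times[neurons == j])
            assert (isi >= R - 1e-9).all()

    def test_no_input_short_horizon_yields_no_decision(self, default_config):
        proto = TrialProtocol(pre_ms=0, max_decision_ms=500, decision_threshold_hz=50)
        for seed in range(5):
            r = run_trial(default_config, None, None, proto, rng=seed, keep_spikes=False)
            assert r.choice == "none" and r.rt_ms is None

    def test_no_decision_checks_before_onset(self, default_config):
        # a decision cannot be reported with rt <= 0 even when the
        # network is already above threshold at onset
        drive = StimulusDrive(mode="coherence", c=0.512)
        proto = TrialProtocol(pre_ms=1000, max_decision_ms=1000, decision_threshold_hz=50)
        r = run_trial(default_config, drive, None, proto, rng=3, keep_spikes=False)
        if r.decided:
            assert r.rt_ms > 0

    def test_zero_amplitude_alpha_reduces_to_plain_engine(self, tiny_config):
        proto = TrialProtocol(pre_ms=100, max_decision_ms=300, decision_threshold_hz=1e9)
        mod = AlphaModulation(amplitude=0.0, frequency_hz=10.0)
        r1 = run_trial(tiny_config, None, None, proto, rng=11, detect=False)
        r2 = run_trial(tiny_config, None, mod, proto, rng=11, detect=False)
        assert np.array_equal(r1.spike_log[0], r2.spike_log[0])
        assert np.array_equal(r1.spike_log[1], r2.spike_log[1])

    def test_frozen_connectivity_is_reused(self, tiny_config, rng):
        from satnet import generate_connectivity

        conn = generate_connectivity(tiny_config, rng)
        proto = TrialProtocol(pre_ms=50, max_decision_ms=200, decision_threshold_hz=1e9)
        r1 = run_trial(tiny_config, None, None, proto, rng=1, conn=conn, detect=False)
        r2 = run_trial(tiny_config, None, None, proto, rng=1, conn=conn, detect=False)
        assert np.array_equal(r1.spike_log[0], r2.spike_log[0])

    def test_rate_series_bounded_by_single_neuron_cap(self, default_config):
        proto = TrialProtocol(pre_ms=0, max_decision_ms=1500, decision_threshold_hz=1e9)
        r = run_trial(default_config, None, None, proto, rng=8, detect=False, keep_spikes=False)
        # 70 Hz cap plus 30-ms window quantization slack
        assert r.rates_A.max() <= 70.0 * (1 + 1.0 / 2) + 1e-9
        assert (r.rates_A >= 0).all() and (r.rates_B >= 0).all()
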
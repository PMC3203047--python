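"""Idealization: noise estimation, change-point recovery, event extraction."""

import numpy as np
import pytest

from singlechan import (
    CurrentTrace,
    IdealizationParams,
    VoltageProtocol,
    estimate_noise_sd,
    extract_gating_events,
    idealize_trace,
)
from singlechan.simulate import default_channel_model, sample_state_path, render_current
from singlechan.io import BufferCondition

from conftest import make_step_trace


class TestEstimateNoiseSd:
    def test_constant_trace_gives_zero(self):
        assert estimate_noise_sd(make_step_trace(np.full(500, 7.0))) == 0.0

    def test_pure_gaussian_within_5pct(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 2.0, 100_000)
        assert estimate_noise_sd(x) == pytest.approx(2.0, rel=0.05)

    def test_robust_to_level_steps(self):
        """50 large steps inflate the naive sd but not the MAD estimate."""
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 2.0, 100_000)
        levels = np.repeat(rng.choice([0.0, 100.0], 51), len(x) // 51 + 1)[: len(x)]
        y = x + levels
        assert np.std(y) > 10.0
        assert estimate_noise_sd(y) == pytest.approx(2.0, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sd(np.zeros(50))


class TestIdealizeTrace:
    def test_noiseless_square_wave_exact(self, ideal_params):
        """10 noiseless transitions -> exactly 11 segments with exact means."""
        seg_len = 50
        x = np.concatenate([
            np.full(seg_len, 100.0 if j % 2 == 0 else 50.0) for j in range(11)
        ])
        ideal = idealize_trace(make_step_trace(x), ideal_params)
        assert ideal.n_segments == 11
        assert np.array_equal(ideal.starts, np.arange(11) * seg_len)
        expected = [100.0 if j % 2 == 0 else 50.0 for j in range(11)]
        assert np.allclose(ideal.means_pA, expected)

    def test_constant_noisy_trace_single_segment(self, ideal_params):
        rng = np.random.default_rng(2)
        tr = make_step_trace(rng.normal(100.0, 2.0, 20_000))
        ideal = idealize_trace(tr, ideal_params)
        assert ideal.n_segments == 1
        assert ideal.means_pA[0] == pytest.approx(100.0, abs=0.1)

    def test_ramp_rejected(self, ideal_params, asymmetric_buffer):
        n = 2000
        proto = VoltageProtocol("ramp", -100.0, 100.0, 1.0)
        t = np.arange(n) / 2000.0
        v = proto.voltage_at(t)
        tr = CurrentTrace(t, v.copy(), v, 2000.0, asymmetric_buffer, proto, "r")
        with pytest.raises(ValueError, match="ramp"):
            idealize_trace(tr, ideal_params)

    def test_recovers_planted_transitions(self, ideal_params):
        """>= 95% of 5-sigma steps with generous dwells found within 2 samples."""
        rng = np.random.default_rng(3)
        fs, sigma, n_trans = 5000.0, 2.0, 200
        dwell = 40  # samples; 8x min_dwell
        levels = np.zeros(n_trans + 1)
        levels[1::2] = 12.0  # 6-sigma steps
        x = np.repeat(levels, dwell) + rng.normal(0, sigma, (n_trans + 1) * dwell)
        ideal = idealize_trace(make_step_trace(x, sample_rate_Hz=fs), ideal_params)
        true_cps = np.arange(1, n_trans + 1) * dwell
        found = np.asarray(ideal.ends[:-1])
        hits = sum(np.min(np.abs(found - cp)) <= 2 for cp in true_cps)
        assert hits / n_trans >= 0.95
        # spurious segments: detected boundaries not near any true transition
        spurious = sum(np.min(np.abs(true_cps - f)) > 2 for f in found)
        assert spurious <= 0.02 * n_trans

    def test_idempotent_on_reconstruction(self, channel_model, ideal_params,
                                          symmetric_buffer):
        proto = VoltageProtocol("step", -100.0, -100.0, 5.0)
        path = sample_state_path(channel_model, 5.0, seed=13)
        tr = render_current(path, channel_model, proto, symmetric_buffer, 5000.0, 14)
        ideal = idealize_trace(tr, ideal_params)
        recon = make_step_trace(ideal.reconstruction(), voltage_mV=-100.0)
        again = idealize_trace(recon, ideal_params)
        assert np.array_equal(ideal.ends, again.ends)
        assert np.allclose(ideal.means_pA, again.means_pA)

    def test_all_segments_respect_min_dwell(self, channel_model, ideal_params,
                                            symmetric_buffer):
        proto = VoltageProtocol("step", 100.0, 100.0, 5.0)
        path = sample_state_path(channel_model, 5.0, seed=15)
        tr = render_current(path, channel_model, proto, symmetric_buffer, 5000.0, 16)
        ideal = idealize_trace(tr, ideal_params)
        min_len = round(ideal_params.min_dwell_s * 5000.0)
        assert np.all(ideal.ends - ideal.starts >= min_len)

    def test_lowering_threshold_never_loses_true_transitions(self):
        """Detection sensitivity is monotone in threshold_k."""
        rng = np.random.default_rng(4)
        dwell = 60
        levels = np.tile([0.0, 9.0], 30)
        x = np.repeat(levels, dwell) + rng.normal(0, 2.0, 60 * dwell)
        tr = make_step_trace(x)
        true_cps = np.arange(1, 60) * dwell
        found_per_k = []
        for k in (6.0, 4.0, 3.0):
            ideal = idealize_trace(tr, IdealizationParams(threshold_k=k))
            found = np.asarray(ideal.ends[:-1])
            hits = sum(
                found.size > 0 and np.min(np.abs(found - cp)) <= 2 for cp in true_cps
            )
            found_per_k.append(hits)
        assert found_per_k == sorted(found_per_k)


class TestExtractGatingEvents:
    def test_unit_conversion_single_step(self, ideal_params):
        """10 pA step at +100 mV, E_rev 0 -> one 100 pS positive event."""
        x = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        tr = make_step_trace(x, voltage_mV=100.0)
        ideal = idealize_trace(tr, ideal_params)
        events = extract_gating_events(ideal, tr, ideal_params)
        assert len(events) == 1
        ev = events[0]
        assert ev.conductance_pS == pytest.approx(100.0)
        assert ev.delta_I_pA == pytest.approx(10.0)
        assert ev.polarity == "positive"
        assert ev.dwell_pre_s == pytest.approx(100 / 5000.0)

    def test_single_segment_yields_no_events(self, ideal_params):
        tr = make_step_trace(np.full(1000, 5.0))
        ideal = idealize_trace(tr, ideal_params)
        assert extract_gating_events(ideal, tr, ideal_params) == []

    def test_events_near_reversal_dropped(self, ideal_params):
        x = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        tr = make_step_trace(x, voltage_mV=5.0)  # |V - E_rev| < 10 mV
        ideal = idealize_trace(tr, ideal_params)
        assert extract_gating_events(ideal, tr, ideal_params) == []

    def test_event_count_matches_segment_count(self, ideal_params):
        """With all steps far above threshold, events = segments - 1."""
        rng = np.random.default_rng(17)
        dwell = 80
        levels = np.tile([-120.0, -96.0], 12)  # 24 pA steps, 12-sigma
        x = np.repeat(levels, dwell) + rng.normal(0, 2.0, 24 * dwell)
        tr = make_step_trace(x, voltage_mV=-120.0)
        ideal = idealize_trace(tr, ideal_params)
        events = extract_gating_events(ideal, tr, ideal_params)
        assert len(events) == ideal.n_segments - 1

    def test_subthreshold_amplitude_boundaries_not_reported(self, channel_model,
                                                            ideal_params,
                                                            symmetric_buffer):
        """Simulated traces may keep statistically significant boundaries of
        small amplitude; those fall below the single-event resolution and
        are excluded from the event list."""
        proto = VoltageProtocol("step", -120.0, -120.0, 5.0)
        path = sample_state_path(channel_model, 5.0, seed=17)
        tr = render_current(path, channel_model, proto, symmetric_buffer, 5000.0, 18)
        ideal = idealize_trace(tr, ideal_params)
        events = extract_gating_events(ideal, tr, ideal_params)
        assert len(events) <= ideal.n_segments - 1
        sigma = 2.0
        for ev in events:
            assert abs(ev.delta_I_pA) >= ideal_params.threshold_k * sigma * 0.9

    def test_mismatched_ideal_and_trace_rejected(self, ideal_params):
        tr1 = make_step_trace(np.zeros(1000), trace_id="a")
        tr2 = make_step_trace(np.zeros(500), trace_id="b")
        ideal = idealize_trace(tr1, ideal_params)
        with pytest.raises(ValueError):
            extract_gating_events(ideal, tr2, ideal_params)

    def test_substate_conductance_recovered(self, ideal_params, symmetric_buffer):
        """Ground-truth 252 pS substate steps at -100 mV recovered within 5%."""
        rng = np.random.default_rng(5)
        fs, v = 5000.0, -100.0
        base, step = -126.0, 25.2  # 252 pS upward steps at -100 mV
        dwell = 100
        levels = np.tile([0.0, step], 40)
        x = base + np.repeat(levels, dwell) + rng.normal(0, 2.0, 80 * dwell)
        tr = make_step_trace(x, voltage_mV=v, sample_rate_Hz=fs)
        ideal = idealize_trace(tr, ideal_params)
        events = extract_gating_events(ideal, tr, ideal_params)
        g = np.array([e.conductance_pS for e in events])
        assert len(g) > 50
        assert g.mean() == pytest.approx(252.0, rel=0.05)
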
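"""Markov gating simulator: dwell statistics, rendering physics, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from singlechan import (
    ASYMMETRIC_BUFFER,
    SYMMETRIC_BUFFER,
    ChannelModel,
    ConductanceLevel,
    SwellingParams,
    VoltageProtocol,
    ghk_reversal_mV,
    render_current,
    sample_state_path,
    simulate_swelling,
    validate_trace,
)


def two_level_model(k12=10.0, k21=10.0, **kw):
    return ChannelModel(
        levels=(ConductanceLevel("open", 1000, 1000), ConductanceLevel("sub", 500, 500)),
        rates_per_s=((0.0, k12), (k21, 0.0)),
        **kw,
    )


class TestSampleStatePath:
    def test_single_level_gives_one_segment(self):
        m = ChannelModel(levels=(ConductanceLevel("o", 100, 100),), rates_per_s=((0.0,),))
        p = sample_state_path(m, 50.0, seed=1)
        assert p.segments == ((0, 0.0, 50.0),)

    def test_absorbing_level_holds_to_end(self):
        m = ChannelModel(
            levels=(ConductanceLevel("a", 1, 1), ConductanceLevel("b", 2, 2)),
            rates_per_s=((0.0, 5.0), (0.0, 0.0)),  # b is absorbing
        )
        p = sample_state_path(m, 100.0, seed=3)
        assert p.segments[-1][0] == 1
        assert p.segments[-1][2] == 100.0

    def test_exponential_dwells_and_occupancy(self):
        """k12 = k21 = 10/s: mean dwell 0.1 s and 50% occupancy, within 3 SE."""
        m = two_level_model()
        p = sample_state_path(m, 1000.0, seed=7)
        dwells = np.array([seg[2] - seg[1] for seg in p.segments[:-1]])
        n = len(dwells)
        assert abs(dwells.mean() - 0.1) < 3 * 0.1 / np.sqrt(n)
        time0 = sum(e - s for lvl, s, e in p.segments if lvl == 0)
        frac = time0 / p.duration_s
        # occupancy SE for alternating renewal with ~n/2 cycles
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n / 2)

    def test_deterministic_given_seed(self):
        m = two_level_model()
        assert sample_state_path(m, 10.0, 99) == sample_state_path(m, 10.0, 99)

    def test_segments_are_contiguous_and_cover_duration(self):
        p = sample_state_path(two_level_model(), 25.0, seed=5)
        assert p.segments[0][1] == 0.0
        assert p.segments[-1][2] == 25.0
        for a, b in zip(p.segments[:-1], p.segments[1:]):
            assert a[2] == b[1]
            assert a[2] > a[1]

    def test_stationary_occupancy_chi2_three_levels(self):
        """Time-sampled occupancy of a 3-level chain matches pi (alpha=0.01)."""
        m = ChannelModel(
            levels=(
                ConductanceLevel("a", 1, 1),
                ConductanceLevel("b", 2, 2),
                ConductanceLevel("c", 3, 3),
            ),
            rates_per_s=((0.0, 4.0, 2.0), (6.0, 0.0, 1.0), (3.0, 2.0, 0.0)),
        )
        path = sample_state_path(m, 1e5, seed=123)
        # 1 s sampling interval >> mixing time (rates are 1-6 /s)
        samples = path.level_at(np.arange(0.5, 1e5, 1.0))
        counts = np.bincount(samples, minlength=3)
        pi = m.stationary_distribution()
        _, pval = stats.chisquare(counts, pi * counts.sum())
        assert pval > 0.01
        # per-level mean dwell = 1 / (sum of outgoing rates), within 3 SE
        q = np.array(m.rates_per_s)
        segs = [(lvl, e - s) for lvl, s, e in path.segments[:-1]]
        for k in range(3):
            d = np.array([dur for lvl, dur in segs if lvl == k])
            expected = 1.0 / q[k].sum()
            assert abs(d.mean() - expected) < 3 * d.std(ddof=1) / np.sqrt(len(d))


class TestRenderCurrent:
    def test_ohms_law_at_fixed_units(self, symmetric_buffer):
        """1000 pS, no noise, +100 mV step, symmetric salt -> 100 pA."""
        m = ChannelModel(
            levels=(ConductanceLevel("o", 1000.0, 1000.0),), rates_per_s=((0.0,),)
        )
        proto = VoltageProtocol("step", 100.0, 100.0, 0.1)
        p = sample_state_path(m, 0.1, 0)
        tr = render_current(p, m, proto, symmetric_buffer, 1000.0, 0)
        assert np.allclose(tr.current_pA, 100.0)

    def test_ramp_current_changes_sign_at_reversal(self, asymmetric_buffer):
        m = two_level_model(permeability_ratio=6.5, noise_sd_pA=0.0)
        e_rev = ghk_reversal_mV(6.5, asymmetric_buffer)
        proto = VoltageProtocol("ramp", -100.0, 100.0, 2.0)
        p = sample_state_path(m, 2.0, 11)
        tr = render_current(p, m, proto, asymmetric_buffer, 2000.0, 0)
        sign = np.sign(tr.current_pA)
        crossings = np.flatnonzero(np.diff(sign) > 0)
        assert len(crossings) == 1
        v_cross = tr.voltage_mV[crossings[0] + 1]
        assert abs(v_cross - e_rev) < 0.1  # one sample of ramp resolution

    def test_mean_current_matches_stationary_prediction(self, channel_model):
        """<I> at fixed V equals sum_i pi_i g_i (V - E_rev)/1000 within MC error."""
        v = -100.0
        proto = VoltageProtocol("step", v, v, 200.0)
        path = sample_state_path(channel_model, 200.0, seed=21)
        tr = render_current(path, channel_model, proto, SYMMETRIC_BUFFER, 1000.0, 22)
        pi = channel_model.stationary_distribution()
        g = np.array([lv.g_neg_pS for lv in channel_model.levels])
        expected = float(pi @ g) * v / 1000.0
        # MC error from 1 s block means (gating is correlated within blocks)
        blocks = tr.current_pA.reshape(200, -1).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(tr.current_pA.mean() - expected) < 4 * se

    def test_rendered_trace_passes_validation(self, channel_model, symmetric_buffer):
        proto = VoltageProtocol("step", -100.0, -100.0, 1.0)
        p = sample_state_path(channel_model, 1.0, 4)
        tr = render_current(p, channel_model, proto, symmetric_buffer, 5000.0, 5)
        assert validate_trace(tr) == []

    def test_bit_reproducible_given_seed(self, channel_model, symmetric_buffer):
        proto = VoltageProtocol("step", 60.0, 60.0, 0.5)
        p = sample_state_path(channel_model, 0.5, 8)
        a = render_current(p, channel_model, proto, symmetric_buffer, 5000.0, 9)
        b = render_current(p, channel_model, proto, symmetric_buffer, 5000.0, 9)
        assert np.array_equal(a.current_pA, b.current_pA)

    def test_path_shorter_than_protocol_rejected(self, channel_model, symmetric_buffer):
        proto = VoltageProtocol("step", 60.0, 60.0, 2.0)
        p = sample_state_path(channel_model, 1.0, 8)
        with pytest.raises(ValueError, match="shorter"):
            render_current(p, channel_model, proto, symmetric_buffer, 1000.0, 0)


class TestModelValidation:
    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            ChannelModel(
                levels=(ConductanceLevel("a", 1, 1), ConductanceLevel("b", 1, 1)),
                rates_per_s=((0.0, -1.0), (1.0, 0.0)),
            )

    def test_rejects_wrong_matrix_shape(self):
        with pytest.raises(ValueError):
            ChannelModel(
                levels=(ConductanceLevel("a", 1, 1),), rates_per_s=((0.0, 1.0),)
            )

    def test_rejects_negative_conductance(self):
        with pytest.raises(ValueError):
            ConductanceLevel("x", -5.0, 10.0)


class TestSimulateSwelling:
    def test_no_recovery_stays_at_dropped_level(self):
        p = SwellingParams(recovery_rate_per_min=0.0, noise_sd_od=0.0)
        tr = simulate_swelling(p)
        post = tr.time_min >= p.salt_time_min
        dropped = p.od_baseline * (1 - p.drop_fraction)
        assert np.allclose(tr.od500[post], dropped)
        assert np.allclose(tr.od500[~post], p.od_baseline)

    def test_recovery_is_monotone_toward_baseline(self):
        p = SwellingParams(recovery_rate_per_min=0.05, noise_sd_od=0.0,
                           duration_min=200.0)
        tr = simulate_swelling(p)
        post = tr.od500[tr.time_min >= p.salt_time_min]
        assert np.all(np.diff(post) > 0)
        assert post[-1] < p.od_baseline
        assert post[-1] > 0.99 * p.od_baseline  # asymptote is the baseline

    def test_deterministic_given_seed(self):
        p = SwellingParams(seed=42)
        assert np.array_equal(simulate_swelling(p).od500, simulate_swelling(p).od500)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SwellingParams(drop_fraction=1.5)
        with pytest.raises(ValueError):
            SwellingParams(salt_time_min=99.0, duration_min=60.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    k12=st.floats(min_value=0.5, max_value=50.0),
    k21=st.floats(min_value=0.5, max_value=50.0),
)
def test_stationary_distribution_solves_balance(k12, k21):
    m = two_level_model(k12=k12, k21=k21)
    pi = m.stationary_distribution()
    assert pi == pytest.approx([k21 / (k12 + k21), k12 / (k12 + k21)], rel=1e-9)
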
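"""Reference study conditions and recovery measurements.

Bundles the full analysis under the recording conditions the package
emulates — symmetric 250 mM KCl step protocol at 15 voltages from -140 to
+140 mV, asymmetric 250/20 mM KCl ramps, a rectifying mostly-open channel
(1260/1010 pS) with substate gating, 2 pA noise — and measures how well
each pipeline stage recovers the simulator's ground truth.  Used by the
acceptance script, the analysis drivers, and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conductance import (
    assign_classes,
    fit_class_iv,
    fully_open_conductance,
)
from .idealize import (
    IdealizationParams,
    events_to_frame,
    extract_gating_events,
    idealize_trace,
)
from .selectivity import find_reversal_potential, ghk_permeability_ratio, ghk_reversal_mV
from .simulate import (
    ASYMMETRIC_BUFFER,
    ChannelModel,
    StatePath,
    SwellingParams,
    default_channel_model,
    simulate_ramp_protocol,
    simulate_step_protocol,
    simulate_swelling,
)
from .swelling import summarize_swelling

#: ground-truth substate step conductances of the reference model (pS)
TRUE_CLASS_SLOPES_PS = {"I": 150.0, "II": 350.0}
TRUE_G_NEG_PS = 1260.0
TRUE_G_POS_PS = 1010.0


@dataclass(frozen=True)
class TransitionRecovery:
    """Detection score against simulator ground truth.

    Counts true gating transitions whose step amplitude is at least
    ``min_sigma`` noise standard deviations and whose flanking dwells are at
    least five minimum dwells, and how many were localized within two
    samples by the idealization.
    """

    n_true: int
    n_found: int
    n_detected_boundaries: int

    @property
    def fraction_found(self) -> float:
        return self.n_found / self.n_true if self.n_true else float("nan")


def _score_transitions(
    ideal, path: StatePath, model: ChannelModel, voltage_mV: float,
    sample_rate_Hz: float, params: IdealizationParams, min_sigma: float = 5.0,
) -> tuple[int, int]:
    g = np.array(
        [lv.g_neg_pS if voltage_mV < 0 else lv.g_pos_pS for lv in model.levels]
    )
    detected = np.asarray(ideal.ends[:-1], dtype=int)
    n_true = n_found = 0
    segs = path.segments
    for j in range(len(segs) - 1):
        pre = segs[j][2] - segs[j][1]
        post = segs[j + 1][2] - segs[j + 1][1]
        amp = abs(g[segs[j + 1][0]] - g[segs[j][0]]) * abs(voltage_mV) / 1000.0
        if (
            amp >= min_sigma * model.noise_sd_pA
            and pre >= 5 * params.min_dwell_s
            and post >= 5 * params.min_dwell_s
        ):
            n_true += 1
            idx = int(round(segs[j][2] * sample_rate_Hz))
            if detected.size and np.min(np.abs(detected - idx)) <= 2:
                n_found += 1
    return n_true, n_found


def run_conductance_study(
    seed: int,
    duration_s: float = 6.0,
    sample_rate_Hz: float = 5000.0,
    noise_sd_pA: float = 2.0,
) -> dict:
    """Simulate the 15-voltage step protocol and run the conductance pipeline.

    Returns the recovered fully open conductances, per-class I-V slopes and
    the ground-truth transition recovery score.
    """
    model = default_channel_model(noise_sd_pA=noise_sd_pA)
    params = IdealizationParams()
    steps = simulate_step_protocol(
        model, duration_s=duration_s, sample_rate_Hz=sample_rate_Hz, seed=seed
    )
    ideals, events = [], []
    n_true = n_found = 0
    for tr, path in steps:
        ideal = idealize_trace(tr, params)
        ideals.append(ideal)
        events.extend(extract_gating_events(ideal, tr, params))
        t, f = _score_transitions(
            ideal, path, model, tr.protocol.v_start_mV, sample_rate_Hz, params
        )
        n_true += t
        n_found += f
    total = fully_open_conductance(ideals)
    classed = assign_classes(events_to_frame(events))
    fits = fit_class_iv(classed)
    recovery = TransitionRecovery(
        n_true=n_true, n_found=n_found,
        n_detected_boundaries=sum(i.n_segments - 1 for i in ideals),
    )
    return {
        "model": model,
        "total_conductance": total,
        "class_fits": fits,
        "classed_events": classed,
        "transition_recovery": recovery,
    }


def run_reversal_study(
    seed: int,
    n_ramps: int = 16,
    duration_s: float = 4.0,
    sample_rate_Hz: float = 2000.0,
    noise_sd_pA: float = 2.0,
) -> dict:
    """Simulate 16 asymmetric-salt ramps and recover the reverse potential."""
    model = default_channel_model(noise_sd_pA=noise_sd_pA)
    ramps = simulate_ramp_protocol(
        model, n_ramps=n_ramps, duration_s=duration_s,
        sample_rate_Hz=sample_rate_Hz, seed=seed,
    )
    est = find_reversal_potential(ramps)
    sel = ghk_permeability_ratio(est.e_rev_mV, ASYMMETRIC_BUFFER)
    return {
        "reversal": est,
        "selectivity": sel,
        "analytic_e_rev_mV": ghk_reversal_mV(model.permeability_ratio, ASYMMETRIC_BUFFER),
    }


def run_swelling_study(seed: int, n_replicates: int = 200) -> dict:
    """Classification accuracy over paired positive/negative swelling replicates.

    Noise spans the 1.5-3% coefficient-of-variation band of replicate
    spread reported for the assay.
    """
    rng = np.random.default_rng(seed)
    n_each = n_replicates // 2
    correct = 0
    for j in range(n_each):
        cv = 0.015 + 0.015 * (j / max(n_each - 1, 1))
        noise = cv * 0.1
        s_pos, s_neg = (int(s) % (2**31) for s in rng.integers(0, 2**31, 2))
        pos = simulate_swelling(
            SwellingParams(recovery_rate_per_min=0.02, noise_sd_od=noise, seed=s_pos)
        )
        neg = simulate_swelling(
            SwellingParams(recovery_rate_per_min=0.0, noise_sd_od=noise, seed=s_neg)
        )
        correct += summarize_swelling(pos).call == "channel_positive"
        correct += summarize_swelling(neg).call == "channel_negative"
    return {"n": 2 * n_each, "accuracy": correct / (2 * n_each)}
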
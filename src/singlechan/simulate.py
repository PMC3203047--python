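"""Continuous-time Markov single-channel simulator.

Generates synthetic planar-bilayer recordings that emulate a mostly-open,
rectifying, cation-selective channel: a fully open conductance level plus
sub-conductance states, exponential dwell times from a transition-rate
matrix, a GHK-determined reversal potential under asymmetric salt, and
white Gaussian recording noise.  Also simulates liposome swelling-assay
OD500 time courses.

All stochastic outputs are bit-reproducible given (inputs, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BufferCondition, CurrentTrace, VoltageProtocol
from .selectivity import ghk_reversal_mV
from .swelling import SwellingTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConductanceLevel:
    """One conductance level with polarity-dependent slope conductance.

    Rectification is modelled as two slope conductances per level:
    ``g_neg_pS`` applies when V < E_rev, ``g_pos_pS`` when V >= E_rev.
    """

    level_id: str
    g_neg_pS: float
    g_pos_pS: float

    def __post_init__(self):
        if self.g_neg_pS < 0 or self.g_pos_pS < 0:
            raise ValueError("slope conductances must be >= 0")


@dataclass(frozen=True)
class ChannelModel:
    """Markov gating model: levels, transition rates, selectivity, noise.

    ``levels[0]`` is the fully open state.  ``rates_per_s[i][j]`` is the
    transition rate from level i to level j (1/s); the diagonal is ignored.
    """

    levels: tuple[ConductanceLevel, ...]
    rates_per_s: tuple[tuple[float, ...], ...]
    permeability_ratio: float = 1.0
    noise_sd_pA: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.levels) < 1:
            raise ValueError("need at least one conductance level")
        q = np.asarray(self.rates_per_s, dtype=float)
        k = len(self.levels)
        if q.shape != (k, k):
            raise ValueError(f"rate matrix must be {k}x{k}, got {q.shape}")
        off = q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if self.permeability_ratio <= 0:
            raise ValueError("permeability_ratio must be > 0")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be >= 0")

    @property
    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q with diagonal = -(row sum of off-diagonals)."""
        q = np.array(self.rates_per_s, dtype=float)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary occupancy pi solving pi Q = 0, sum(pi) = 1."""
        q = self.rate_matrix
        k = q.shape[0]
        a = np.vstack([q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return pi


@dataclass(frozen=True)
class StatePath:
    """Latent gating path: contiguous (level_index, start_s, end_s) segments."""

    segments: tuple[tuple[int, float, float], ...]

    @property
    def duration_s(self) -> float:
        return self.segments[-1][2]

    def level_at(self, times_s: np.ndarray) -> np.ndarray:
        """Level index occupied at each time (right-open segments)."""
        ends = np.array([seg[2] for seg in self.segments])
        levels = np.array([seg[0] for seg in self.segments])
        idx = np.searchsorted(ends, np.asarray(times_s), side="right")
        idx = np.clip(idx, 0, len(levels) - 1)
        return levels[idx]


def sample_state_path(model: ChannelModel, duration_s: float, seed: int) -> StatePath:
    """Exact stochastic simulation of the gating Markov chain.

    Dwell in level i is exponential with rate = sum of outgoing rates from
    i; the next level is chosen with probability proportional to its rate.
    Deterministic given (model, seed).  An absorbing level simply holds to
    the end of the path.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    k = len(model.levels)
    q = np.array(model.rates_per_s, dtype=float)
    np.fill_diagonal(q, 0.0)
    exit_rates = q.sum(axis=1)

    segments: list[tuple[int, float, float]] = []
    state = 0
    t = 0.0
    while t < duration_s:
        rate = exit_rates[state]
        if rate <= 0.0 or k == 1:
            segments.append((state, t, duration_s))
            break
        dwell = rng.exponential(1.0 / rate)
        end = min(t + dwell, duration_s)
        segments.append((state, t, end))
        if end >= duration_s:
            break
        state = int(rng.choice(k, p=q[state] / rate))
        t = end
    return StatePath(segments=tuple(segments))


def render_current(
    path: StatePath,
    model: ChannelModel,
    protocol: VoltageProtocol,
    buffer: BufferCondition,
    sample_rate_Hz: float,
    seed: int,
    trace_id: str = "sim",
) -> CurrentTrace:
    """Render a gating path into a sampled, noisy current trace.

    Per sample: I_pA = g_level(polarity) * (V_mV - E_rev_mV) / 1000 plus
    Gaussian noise, with E_rev from the GHK voltage equation (0 under a
    symmetric buffer) and the polarity branch chosen by sign of (V - E_rev).
    """
    if path.duration_s < protocol.duration_s - 1e-12:
        raise ValueError("state path shorter than the protocol duration")
    n = int(round(protocol.duration_s * sample_rate_Hz))
    if n < 1:
        raise ValueError("protocol too short for the sample rate")
    times = np.arange(n) / sample_rate_Hz
    volts = protocol.voltage_at(times)

    e_rev = 0.0 if buffer.is_symmetric else ghk_reversal_mV(model.permeability_ratio, buffer)
    levels = path.level_at(times)
    g_neg = np.array([lv.g_neg_pS for lv in model.levels])
    g_pos = np.array([lv.g_pos_pS for lv in model.levels])
    g = np.where(volts < e_rev, g_neg[levels], g_pos[levels])
    current = g * (volts - e_rev) / 1000.0

    shortest = min(seg[2] - seg[1] for seg in path.segments)
    if shortest < 1.0 / sample_rate_Hz:
        logger.warning(
            "shortest dwell %.3g s below sample interval %.3g s; brief events "
            "may be aliased", shortest, 1.0 / sample_rate_Hz,
        )
    if model.noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, model.noise_sd_pA, size=n)

    return CurrentTrace(
        time_s=times,
        current_pA=current,
        voltage_mV=volts,
        sample_rate_Hz=sample_rate_Hz,
        buffer=buffer,
        protocol=protocol,
        trace_id=trace_id,
    )


# ---------------------------------------------------------------------------
# study-condition defaults

#: symmetric recording buffer used for conductance measurements
SYMMETRIC_BUFFER = BufferCondition(kcl_cis_mM=250.0, kcl_trans_mM=250.0)

#: asymmetric buffer used for selectivity ramps (concentrated salt on cis)
ASYMMETRIC_BUFFER = BufferCondition(kcl_cis_mM=250.0, kcl_trans_mM=20.0)

#: the 15-voltage step protocol, -140..+140 mV in 20 mV increments
STEP_VOLTAGES_MV = tuple(float(v) for v in range(-140, 141, 20))


def default_channel_model(noise_sd_pA: float = 2.0, seed: int = 0) -> ChannelModel:
    """Reference rectifying channel: fully open level plus two substates.

    The fully open level carries 1260/1010 pS at negative/positive
    potential.  Gating events are excursions to substates 150 pS and
    350 pS below the open level, so event amplitudes fall in the two
    conductance classes on either side of the 220/180 pS thresholds.
    Occupancy of the open level is ~93%.
    """
    levels = (
        ConductanceLevel("open", 1260.0, 1010.0),
        ConductanceLevel("sub150", 1110.0, 860.0),
        ConductanceLevel("sub350", 910.0, 660.0),
    )
    rates = (
        (0.0, 2.0, 1.0),
        (40.0, 0.0, 0.0),
        (40.0, 0.0, 0.0),
    )
    return ChannelModel(
        levels=levels,
        rates_per_s=rates,
        permeability_ratio=6.5,
        noise_sd_pA=noise_sd_pA,
        seed=seed,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit substream seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_step_protocol(
    model: ChannelModel,
    voltages_mV=STEP_VOLTAGES_MV,
    duration_s: float = 6.0,
    sample_rate_Hz: float = 5000.0,
    buffer: BufferCondition = SYMMETRIC_BUFFER,
    seed: int = 0,
) -> list[tuple[CurrentTrace, StatePath]]:
    """One constant-voltage recording per listed potential, with ground truth."""
    out = []
    seeds = _child_seeds(seed, 2 * len(tuple(voltages_mV)))
    for j, v in enumerate(voltages_mV):
        proto = VoltageProtocol("step", v, v, duration_s)
        path = sample_state_path(model, duration_s, seeds[2 * j])
        tr = render_current(
            path, model, proto, buffer, sample_rate_Hz, seeds[2 * j + 1],
            trace_id=f"step_{int(round(v)):+04d}mV",
        )
        out.append((tr, path))
    return out


def simulate_ramp_protocol(
    model: ChannelModel,
    n_ramps: int = 16,
    v_range_mV: tuple[float, float] = (-100.0, 100.0),
    duration_s: float = 4.0,
    sample_rate_Hz: float = 2000.0,
    buffer: BufferCondition = ASYMMETRIC_BUFFER,
    seed: int = 0,
) -> list[CurrentTrace]:
    """Alternating-direction voltage ramps under the salt gradient."""
    out = []
    seeds = _child_seeds(seed, 2 * n_ramps)
    lo, hi = v_range_mV
    for j in range(n_ramps):
        v0, v1 = (lo, hi) if j % 2 == 0 else (hi, lo)
        proto = VoltageProtocol("ramp", v0, v1, duration_s)
        path = sample_state_path(model, duration_s, seeds[2 * j])
        out.append(
            render_current(
                path, model, proto, buffer, sample_rate_Hz, seeds[2 * j + 1],
                trace_id=f"ramp_{j:02d}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# liposome swelling assay

@dataclass(frozen=True)
class SwellingParams:
    """Parameters of a simulated OD500 swelling time course.

    After salt addition the optical density drops instantaneously by
    ``drop_fraction`` (osmotic shrinkage), then relaxes back toward
    baseline at first order with ``recovery_rate_per_min`` (0 for
    channel-free liposomes, which stay shrunken).
    """

    od_baseline: float = 0.1
    drop_fraction: float = 0.2
    recovery_rate_per_min: float = 0.02
    noise_sd_od: float = 0.002
    salt_time_min: float = 10.0
    duration_min: float = 60.0
    seed: int = 0
    label: str = "sim"

    def __post_init__(self):
        if self.od_baseline <= 0:
            raise ValueError("od_baseline must be > 0")
        if not (0 <= self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in [0, 1)")
        if self.recovery_rate_per_min < 0 or self.noise_sd_od < 0:
            raise ValueError("rates and noise must be >= 0")
        if not (0 < self.salt_time_min < self.duration_min):
            raise ValueError("salt_time_min must fall inside the recording")


def simulate_swelling(params: SwellingParams) -> SwellingTrace:
    """OD500 read every minute; deterministic given (params, params.seed)."""
    t = np.arange(0.0, params.duration_min + 0.5, 1.0)
    od = np.full_like(t, params.od_baseline)
    post = t >= params.salt_time_min
    drop = params.od_baseline * params.drop_fraction
    od[post] = params.od_baseline - drop * np.exp(
        -params.recovery_rate_per_min * (t[post] - params.salt_time_min)
    )
    if params.noise_sd_od > 0:
        rng = np.random.default_rng(params.seed)
        od = od + rng.normal(0.0, params.noise_sd_od, size=len(t))
    return SwellingTrace(
        time_min=t, od500=od, salt_time_min=params.salt_time_min, label=params.label
    )
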
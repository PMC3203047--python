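"""Current-trace idealization and gating-event extraction.

Reduces a noisy constant-voltage recording to a piecewise-constant fit
(levels and transition times), then turns each level transition into a
gating event whose conductance is |dI| / |V - E_rev|.

Detection is a two-pass procedure: candidate change points are samples
where the difference of adjacent sliding-window means exceeds
``threshold_k`` times a robust noise estimate, refined to the sample of
maximal local difference; segments shorter than the minimum resolvable
dwell are merged into the neighbor with the closer mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CurrentTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdealizationParams:
    """Detection settings for trace idealization.

    ``threshold_k`` is the step-detection threshold in multiples of the
    robust noise sd; ``min_dwell_s`` the shortest dwell retained;
    ``e_rev_assumed_mV`` the reversal used to convert step amplitudes to
    conductances (0 under a symmetric buffer).  ``window_s`` is the
    sliding-mean half-window; by default equal to the minimum dwell.
    """

    threshold_k: float = 4.0
    min_dwell_s: float = 1e-3
    e_rev_assumed_mV: float = 0.0
    window_s: float | None = None

    def __post_init__(self):
        if self.threshold_k <= 0 or self.min_dwell_s <= 0:
            raise ValueError("threshold_k and min_dwell_s must be > 0")


@dataclass
class IdealizedTrace:
    """Piecewise-constant fit: contiguous (start, end, mean) segments."""

    starts: np.ndarray  # segment start sample (inclusive)
    ends: np.ndarray  # segment end sample (exclusive)
    means_pA: np.ndarray
    trace_id: str
    voltage_mV: float
    sample_rate_Hz: float
    params: IdealizationParams

    @property
    def n_segments(self) -> int:
        return len(self.means_pA)

    def reconstruction(self, n_samples: int | None = None) -> np.ndarray:
        """The piecewise-constant signal implied by the segments."""
        n = int(self.ends[-1]) if n_samples is None else n_samples
        out = np.empty(n)
        for s, e, m in zip(self.starts, self.ends, self.means_pA):
            out[int(s) : int(e)] = m
        return out


@dataclass(frozen=True)
class GatingEvent:
    """One idealized current transition.

    ``conductance_pS`` = |dI| * 1000 / |V - E_rev_assumed|; polarity is the
    sign of the command potential.
    """

    time_s: float
    voltage_mV: float
    delta_I_pA: float
    conductance_pS: float
    polarity: str  # "negative" | "positive"
    dwell_pre_s: float
    dwell_post_s: float


def estimate_noise_sd(trace: CurrentTrace | np.ndarray) -> float:
    """Robust noise sd (pA) from the MAD of first differences.

    Insensitive to level steps: sd = MAD(diff(I)) / (sqrt(2) * 0.6745).
    """
    x = trace.current_pA if isinstance(trace, CurrentTrace) else np.asarray(trace, float)
    if len(x) < 100:
        raise ValueError(f"need >= 100 samples for a noise estimate, got {len(x)}")
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / (math.sqrt(2.0) * 0.6745))


def _detect_changepoints(x: np.ndarray, w: int, thr: float) -> list[int]:
    """Binary segmentation on the sliding-mean-difference statistic.

    Each interval is split at the sample of maximal |d| when that maximum
    exceeds the threshold, then both halves are re-examined.  Recursing
    keeps closely spaced same-direction steps (staircases) separable down
    to one window length, and makes the detected set grow monotonically as
    the threshold is lowered.
    """
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * w:
            continue
        i = np.arange(lo + w, hi - w + 1)
        d = (c[i + w] - c[i]) / w - (c[i] - c[i - w]) / w
        j = int(np.argmax(np.abs(d)))
        if abs(d[j]) <= thr:
            continue
        cp = int(i[j])
        cps.append(cp)
        stack.append((lo, cp))
        stack.append((cp, hi))
    return sorted(cps)


def _merge_short_segments(
    bounds: list[int], x: np.ndarray, min_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge sub-min_dwell segments into the neighbor with the closer mean."""
    starts = np.array(bounds[:-1])
    ends = np.array(bounds[1:])

    def seg_means(s, e):
        c = np.concatenate(([0.0], np.cumsum(x)))
        return (c[e] - c[s]) / (e - s)

    means = seg_means(starts, ends)
    while len(starts) > 1:
        lengths = ends - starts
        short = np.flatnonzero(lengths < min_len)
        if short.size == 0:
            break
        j = int(short[np.argmin(lengths[short])])
        if j == 0:
            k = 1
        elif j == len(starts) - 1:
            k = j - 1
        else:
            k = j - 1 if abs(means[j - 1] - means[j]) <= abs(means[j + 1] - means[j]) else j + 1
        lo, hi = min(j, k), max(j, k)
        starts = np.delete(starts, hi)
        ends = np.delete(ends, lo)
        means = seg_means(starts, ends)
    return starts, ends, means


def idealize_trace(trace: CurrentTrace, params: IdealizationParams) -> IdealizedTrace:
    """Piecewise-constant idealization of a constant-voltage recording.

    Every true step of amplitude >= threshold_k * sigma lasting at least the
    minimum dwell is represented; sub-dwell segments are merged into the
    neighbor with the closer mean; boundaries whose mean difference is not
    significant at the achieved averaging length are dropped.  Deterministic.
    Ramp recordings are rejected (idealization assumes a constant driving
    force).
    """
    if trace.protocol.kind != "step":
        raise ValueError("only step-protocol traces are idealized; got ramp")
    x = trace.current_pA
    n = len(x)
    fs = trace.sample_rate_Hz
    min_len = max(2, int(round(params.min_dwell_s * fs)))
    window_s = params.window_s if params.window_s is not None else params.min_dwell_s
    w = max(3, int(round(window_s * fs)))
    w = min(w, max(2, n // 2 - 1))

    if n >= 100:
        sigma = estimate_noise_sd(x)
    else:
        sigma = 0.0
    # absolute floor keeps float rounding from fragmenting noiseless traces
    thr = max(params.threshold_k * sigma, 1e-9 * (1.0 + float(np.max(np.abs(x)))))

    cps = _detect_changepoints(x, w, thr)
    bounds = sorted({0, n, *[cp for cp in cps if 0 < cp < n]})
    starts, ends, means = _merge_short_segments(list(bounds), x, min_len)

    # drop boundaries that are not significant at the precision of the
    # segment means: |gap| must exceed k * sigma * sqrt(1/n_i + 1/n_j)
    # (with the same absolute floor).  Weakest boundary first.
    c = np.concatenate(([0.0], np.cumsum(x)))
    while len(means) > 1:
        lens = (ends - starts).astype(float)
        need = np.maximum(
            params.threshold_k * sigma * np.sqrt(1.0 / lens[:-1] + 1.0 / lens[1:]),
            1e-9 * (1.0 + float(np.max(np.abs(x)))),
        )
        margin = np.abs(np.diff(means)) - need
        j = int(np.argmin(margin))
        if margin[j] >= 0:
            break
        starts = np.delete(starts, j + 1)
        ends = np.delete(ends, j)
        means = (c[ends] - c[starts]) / (ends - starts)

    # final level estimates exclude one sample at each boundary: the sample
    # containing the transition takes an intermediate value and would
    # attenuate step amplitudes
    trim = (ends - starts) >= 4
    lo = starts + np.where(trim, 1, 0)
    hi = ends - np.where(trim, 1, 0)
    means = (c[hi] - c[lo]) / (hi - lo)

    return IdealizedTrace(
        starts=starts,
        ends=ends,
        means_pA=means,
        trace_id=trace.trace_id,
        voltage_mV=float(trace.protocol.v_start_mV),
        sample_rate_Hz=fs,
        params=params,
    )


#: events closer to the assumed reversal than this are dropped — the
#: conductance conversion divides by (V - E_rev) and becomes ill-conditioned
MIN_DRIVING_FORCE_MV = 10.0


def extract_gating_events(
    ideal: IdealizedTrace, trace: CurrentTrace, params: IdealizationParams
) -> list[GatingEvent]:
    """One gating event per adjacent segment pair of the idealization.

    Transitions whose amplitude falls below the raw-sample detection
    threshold (threshold_k * noise sd) are not reported as gating events —
    the idealization may retain such boundaries when long segments make a
    small mean difference statistically significant, but they are below the
    resolution claimed for single events.  Likewise, transitions flanked by
    a dwell shorter than twice the minimum dwell are dropped: their level
    means are dominated by transition samples, so the step amplitude cannot
    be measured reliably (the usual dead-time rule for amplitude analysis).
    """
    if ideal.trace_id != trace.trace_id or int(ideal.ends[-1]) != len(trace):
        raise ValueError("idealization does not correspond to the given trace")
    sigma = estimate_noise_sd(trace) if len(trace) >= 100 else 0.0
    min_amp = params.threshold_k * sigma
    events: list[GatingEvent] = []
    fs = ideal.sample_rate_Hz
    for j in range(ideal.n_segments - 1):
        t_idx = int(ideal.ends[j])
        v = float(trace.voltage_mV[min(t_idx, len(trace) - 1)])
        drive = v - params.e_rev_assumed_mV
        if abs(drive) < MIN_DRIVING_FORCE_MV:
            continue
        delta = float(ideal.means_pA[j + 1] - ideal.means_pA[j])
        if abs(delta) < min_amp:
            continue
        dwell_pre = float(ideal.ends[j] - ideal.starts[j]) / fs
        dwell_post = float(ideal.ends[j + 1] - ideal.starts[j + 1]) / fs
        if min(dwell_pre, dwell_post) < 2.0 * params.min_dwell_s:
            continue
        events.append(
            GatingEvent(
                time_s=float(trace.time_s[min(t_idx, len(trace) - 1)]),
                voltage_mV=v,
                delta_I_pA=delta,
                conductance_pS=abs(delta) * 1000.0 / abs(drive),
                polarity="negative" if v < 0 else "positive",
                dwell_pre_s=dwell_pre,
                dwell_post_s=dwell_post,
            )
        )
    return events


def events_to_frame(events: list[GatingEvent]) -> pd.DataFrame:
    """Gating events as a tidy table (one row per transition)."""
    cols = [
        "time_s", "voltage_mv", "delta_i_pa", "conductance_ps",
        "polarity", "dwell_pre_s", "dwell_post_s",
    ]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        {
            "time_s": [e.time_s for e in events],
            "voltage_mv": [e.voltage_mV for e in events],
            "delta_i_pa": [e.delta_I_pA for e in events],
            "conductance_ps": [e.conductance_pS for e in events],
            "polarity": [e.polarity for e in events],
            "dwell_pre_s": [e.dwell_pre_s for e in events],
            "dwell_post_s": [e.dwell_post_s for e in events],
        }
    )
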
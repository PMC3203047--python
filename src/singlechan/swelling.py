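"""Liposome swelling-assay analysis.

An osmotic shock (salt addition) shrinks vesicles, dropping the optical
density at 500 nm.  If the reconstituted protein forms an ion-permeable
channel, solute influx re-equilibrates the vesicles and the OD recovers
steadily; protein-free (or channel-free) liposomes stay at the dropped
level.  The summary turns one OD500 time course into a baseline, a
post-salt minimum and a recovery slope, and calls channel presence from
the slope's significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SwellingTrace:
    """OD500 time course with the salt-addition time mark."""

    time_min: np.ndarray
    od500: np.ndarray
    salt_time_min: float
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "time_min", np.asarray(self.time_min, dtype=float))
        object.__setattr__(self, "od500", np.asarray(self.od500, dtype=float))
        if len(self.time_min) != len(self.od500):
            raise ValueError("time and OD series must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od500 < 0):
            raise ValueError("OD500 must be >= 0")
        if not (self.time_min[0] <= self.salt_time_min <= self.time_min[-1]):
            raise ValueError("salt_time_min outside the recorded time range")


@dataclass(frozen=True)
class SwellingSummary:
    """Baseline, post-salt minimum, recovery slope, and the channel call."""

    od_baseline: float
    od_min: float
    recovery_slope_per_min: float
    slope_se_per_min: float
    call: str  # "channel_positive" | "channel_negative"
    label: str = ""


def summarize_swelling(
    trace: SwellingTrace, slope_threshold_per_min: float | None = None
) -> SwellingSummary:
    """Summarize one swelling time course and call channel presence.

    Baseline is the mean OD before salt addition; the recovery slope is the
    least-squares slope from the post-salt minimum to the end of the
    recording.  The call is channel_positive iff the slope exceeds
    ``slope_threshold_per_min``; by default the threshold is three standard
    errors of the fitted slope (a signal-significance rule).
    """
    pre = trace.time_min < trace.salt_time_min
    post = ~pre
    if pre.sum() < 3 or post.sum() < 5:
        raise ValueError(
            f"need >=3 pre-salt and >=5 post-salt samples, got "
            f"{int(pre.sum())}/{int(post.sum())}"
        )
    baseline = float(trace.od500[pre].mean())
    t_post = trace.time_min[post]
    od_post = trace.od500[post]
    imin = int(np.argmin(od_post))
    od_min = float(od_post[imin])

    t_win = t_post[imin:]
    od_win = od_post[imin:]
    if len(t_win) < 3:
        slope, se = 0.0, float("inf")
    else:
        fit = stats.linregress(t_win, od_win)
        slope, se = float(fit.slope), float(fit.stderr)

    threshold = 3.0 * se if slope_threshold_per_min is None else slope_threshold_per_min
    call = "channel_positive" if slope > threshold else "channel_negative"
    return SwellingSummary(
        od_baseline=baseline,
        od_min=od_min,
        recovery_slope_per_min=slope,
        slope_se_per_min=se,
        call=call,
        label=trace.label,
    )
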
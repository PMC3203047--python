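"""Conductance histograms, class assignment, per-class I-V fits, and the
fully open (total) conductance per polarity.

Gating events are split into two conductance classes per polarity by a
fixed threshold (class II at or above it, class I below), each class gets
an ordinary least-squares I-V line, and the fully open conductance is the
through-origin slope of the maximal-|current| level across the step
protocol — through the origin because the recording buffer is symmetric,
so the reversal potential is 0 mV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .idealize import IdealizedTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassDef:
    """Conductance-class boundary for one polarity: class II iff g >= threshold."""

    polarity: str  # "negative" | "positive"
    threshold_pS: float

    def __post_init__(self):
        if self.threshold_pS <= 0:
            raise ValueError("threshold_pS must be > 0")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def default_class_defs() -> tuple[ClassDef, ClassDef]:
    """Class thresholds: 220 pS at negative and 180 pS at positive potentials."""
    return (ClassDef("negative", 220.0), ClassDef("positive", 180.0))


def assign_classes(events: pd.DataFrame, defs=None) -> pd.DataFrame:
    """Annotate an events table with a ``class_id`` column ('I' or 'II').

    Every event must have its polarity covered by exactly one ClassDef.
    Returns a copy; the partition is exhaustive and exclusive.
    """
    if defs is None:
        defs = default_class_defs()
    by_pol = {}
    for d in defs:
        if d.polarity in by_pol:
            raise ValueError(f"duplicate ClassDef for polarity {d.polarity!r}")
        by_pol[d.polarity] = d.threshold_pS
    out = events.copy()
    missing = set(out["polarity"]) - set(by_pol)
    if missing:
        raise ValueError(f"no ClassDef for polarity: {sorted(missing)}")
    thr = out["polarity"].map(by_pol)
    out["class_id"] = np.where(out["conductance_ps"] >= thr, "II", "I")
    return out


@dataclass(frozen=True)
class ConductanceHistogram:
    """Event-conductance histogram for one polarity (left-closed bins)."""

    polarity: str
    bin_edges_pS: np.ndarray
    counts: np.ndarray


def conductance_histogram(
    events: pd.DataFrame, polarity: str, bin_width_pS: float = 25.0
) -> ConductanceHistogram:
    """Histogram of event conductances from 0 in fixed-width bins.

    Counts are conserved: their sum equals the number of events of that
    polarity.  An empty selection yields a zero-bin histogram.
    """
    if bin_width_pS <= 0:
        raise ValueError("bin_width_pS must be > 0")
    g = events.loc[events["polarity"] == polarity, "conductance_ps"].to_numpy()
    if g.size == 0:
        return ConductanceHistogram(polarity, np.zeros(0), np.zeros(0, dtype=int))
    n_bins = int(np.ceil((g.max() + 1e-12) / bin_width_pS))
    edges = np.arange(n_bins + 1) * bin_width_pS
    counts, _ = np.histogram(g, bins=edges)
    return ConductanceHistogram(polarity, edges, counts)


@dataclass(frozen=True)
class ClassFit:
    """OLS I-V line of one (polarity, class): slope in pS, free intercept."""

    polarity: str
    class_id: str
    slope_conductance_pS: float
    intercept_pA: float
    n_events: int
    r_squared: float


def fit_class_iv(classed_events: pd.DataFrame) -> list[ClassFit]:
    """Per-(polarity, class) least-squares I-V line over gating events.

    The response is the event amplitude |dI| signed by polarity, so a class
    of constant step conductance falls on a line through the origin with
    slope equal to that conductance.  Classes with fewer than two events
    (or no voltage spread) are skipped with a warning.
    """
    fits: list[ClassFit] = []
    for (pol, cls), grp in classed_events.groupby(["polarity", "class_id"], sort=True):
        if len(grp) < 2:
            logger.warning("class (%s, %s) has %d event(s); skipped", pol, cls, len(grp))
            continue
        v = grp["voltage_mv"].to_numpy()
        y = np.sign(v) * np.abs(grp["delta_i_pa"].to_numpy())
        if np.ptp(v) == 0:
            logger.warning("class (%s, %s) has no voltage spread; skipped", pol, cls)
            continue
        res = stats.linregress(v, y)
        fits.append(
            ClassFit(
                polarity=pol,
                class_id=cls,
                slope_conductance_pS=float(res.slope * 1000.0),
                intercept_pA=float(res.intercept),
                n_events=len(grp),
                r_squared=float(res.rvalue**2),
            )
        )
    return fits


@dataclass(frozen=True)
class TotalConductance:
    """Fully open conductance per polarity with standard errors (pS)."""

    g_neg_pS: float
    g_pos_pS: float
    se_neg_pS: float
    se_pos_pS: float
    n_voltages_per_polarity: tuple[int, int]


def _through_origin_fit(v_mV: np.ndarray, i_pA: np.ndarray) -> tuple[float, float]:
    """Slope (pS) and its SE for I = g V / 1000 with no intercept."""
    sxx = float(np.sum(v_mV * v_mV))
    slope = float(np.sum(v_mV * i_pA)) / sxx  # pA/mV
    n = len(v_mV)
    if n > 1:
        resid = i_pA - slope * v_mV
        se = float(np.sqrt(np.sum(resid**2) / (n - 1) / sxx))
    else:
        se = 0.0
    return slope * 1000.0, se * 1000.0


def fully_open_conductance(
    ideals: list[IdealizedTrace], min_abs_voltage_mV: float = 10.0
) -> TotalConductance:
    """Fully open conductance per polarity from idealized step recordings.

    For each voltage the fully open level is the idealized segment with the
    largest |mean current|; per polarity the (V, I_open) points are fit
    through the origin (symmetric buffer, E_rev = 0).  Needs at least three
    usable voltages of each polarity.
    """
    pts: dict[str, list[tuple[float, float]]] = {"negative": [], "positive": []}
    for ideal in ideals:
        v = ideal.voltage_mV
        if abs(v) < min_abs_voltage_mV:
            logger.warning(
                "trace %s at %g mV excluded: fully open level not identifiable "
                "near 0 mV", ideal.trace_id, v,
            )
            continue
        i_open = float(ideal.means_pA[np.argmax(np.abs(ideal.means_pA))])
        pts["negative" if v < 0 else "positive"].append((v, i_open))
    for pol, p in pts.items():
        if len(p) < 3:
            raise ValueError(
                f"need >= 3 usable voltages at {pol} polarity, got {len(p)}"
            )
    out: dict[str, tuple[float, float]] = {}
    for pol, p in pts.items():
        v = np.array([q[0] for q in p])
        i = np.array([q[1] for q in p])
        out[pol] = _through_origin_fit(v, i)
    return TotalConductance(
        g_neg_pS=out["negative"][0],
        g_pos_pS=out["positive"][0],
        se_neg_pS=out["negative"][1],
        se_pos_pS=out["positive"][1],
        n_voltages_per_polarity=(len(pts["negative"]), len(pts["positive"])),
    )
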
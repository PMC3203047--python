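"""Reverse-potential extraction, GHK selectivity, Nernst reference, and
Hille pore-size estimation.

For a single binary salt (KCl) the Goldman-Hodgkin-Katz voltage equation

    E_rev = (RT/F) ln[(r C_cis + C_trans) / (r C_trans + C_cis)],   r = P_K/P_Cl

is invertible in closed form for the cation:anion permeability ratio.  The
sign convention follows the trace format: potential is cis relative to
trans, so with the concentrated salt on the cis side a cation-selective
channel reverses at positive potential.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import FARADAY, R_GAS
from .io import BufferCondition, CurrentTrace

logger = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    """No usable estimate could be formed from the supplied recordings."""


# ---------------------------------------------------------------------------
# closed-form electrochemistry

def nernst_potential_mV(
    c_cis_mM: float, c_trans_mM: float, valence: int, temperature_K: float
) -> float:
    """Nernst equilibrium potential (mV): (RT/zF) ln(C_cis/C_trans)."""
    if c_cis_mM <= 0 or c_trans_mM <= 0:
        raise ValueError("concentrations must be > 0")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    return 1e3 * R_GAS * temperature_K / (valence * FARADAY) * math.log(c_cis_mM / c_trans_mM)


def ghk_reversal_mV(permeability_ratio: float, buffer: BufferCondition) -> float:
    """GHK zero-current potential (mV) for a KCl gradient.

    ``permeability_ratio`` is r = P_K/P_Cl.  Symmetric buffers and r = 1
    both give exactly 0 mV.
    """
    if permeability_ratio <= 0:
        raise ValueError("permeability_ratio must be > 0")
    cc, ct = buffer.kcl_cis_mM, buffer.kcl_trans_mM
    if cc == ct or permeability_ratio == 1.0:
        # exact zeros, avoiding log-rounding
        num = permeability_ratio * cc + ct
        den = permeability_ratio * ct + cc
        if num == den:
            return 0.0
    rt_f = 1e3 * R_GAS * buffer.temperature_K / FARADAY
    return rt_f * math.log(
        (permeability_ratio * cc + ct) / (permeability_ratio * ct + cc)
    )


@dataclass(frozen=True)
class SelectivityResult:
    """Cation:anion permeability ratio inferred from a reverse potential."""

    permeability_ratio: float
    e_rev_used_mV: float
    buffer: BufferCondition


def ghk_permeability_ratio(e_rev_mV: float, buffer: BufferCondition) -> SelectivityResult:
    """Invert the GHK voltage equation for r = P_K/P_Cl.

    Exact inverse of :func:`ghk_reversal_mV`.  |E_rev| must lie strictly
    inside the Nernst bounds of the gradient, else the inversion has no
    positive solution.
    """
    cc, ct = buffer.kcl_cis_mM, buffer.kcl_trans_mM
    if buffer.is_symmetric:
        raise ValueError("permeability ratio is undefined under a symmetric buffer")
    xi = math.exp(
        e_rev_mV * 1e-3 * FARADAY / (R_GAS * buffer.temperature_K)
    )
    lo, hi = sorted((ct / cc, cc / ct))
    if not (lo < xi < hi):
        e_k = nernst_potential_mV(cc, ct, +1, buffer.temperature_K)
        raise ValueError(
            f"E_rev={e_rev_mV} mV outside the admissible interval: |E_rev| must "
            f"be below the K+ Nernst potential {abs(e_k):.3g} mV for this gradient"
        )
    r = (xi * cc - ct) / (cc - xi * ct)
    return SelectivityResult(permeability_ratio=r, e_rev_used_mV=e_rev_mV, buffer=buffer)


# ---------------------------------------------------------------------------
# reverse potential from voltage ramps

@dataclass(frozen=True)
class ReversalEstimate:
    """Zero-current potential pooled over voltage ramps."""

    e_rev_mV: float
    sem_mV: float
    n_ramps: int
    per_ramp_mV: tuple[float, ...]


def _ramp_zero_crossing(trace: CurrentTrace, smooth_window_mV: float) -> float | None:
    """Median zero-current crossing (mV) of one smoothed ramp, or None."""
    v = trace.voltage_mV
    i = trace.current_pA
    span = abs(trace.protocol.v_end_mV - trace.protocol.v_start_mV)
    if span <= 0:
        return None
    # samples covered by the smoothing window
    w = max(1, int(round(smooth_window_mV / span * len(v))))
    if w > 1:
        kernel = np.ones(w) / w
        i = np.convolve(i, kernel, mode="valid")
        v = np.convolve(v, kernel, mode="valid")
    sign = np.sign(i)
    crossings = []
    for j in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        # linear interpolation in (I, V) between bracketing samples
        di = i[j + 1] - i[j]
        if di == 0:
            continue
        crossings.append(v[j] - i[j] * (v[j + 1] - v[j]) / di)
    zero = np.flatnonzero(sign == 0)
    crossings.extend(v[zero])
    if not crossings:
        return None
    return float(np.median(crossings))


def find_reversal_potential(
    ramps: list[CurrentTrace], smooth_window_mV: float = 5.0
) -> ReversalEstimate:
    """Pool the zero-current potential over asymmetric-salt voltage ramps.

    Each ramp is smoothed with a moving average spanning
    ``smooth_window_mV`` of command potential; the median crossing is taken
    if a ramp crosses zero more than once.  Ramps with no crossing are
    excluded with a warning.
    """
    if not ramps:
        raise ValueError("need at least one ramp")
    per_ramp: list[float] = []
    for tr in ramps:
        if tr.protocol.kind != "ramp":
            raise ValueError(f"trace {tr.trace_id!r} is not a ramp recording")
        if tr.buffer.is_symmetric:
            raise ValueError(
                f"trace {tr.trace_id!r} was recorded under a symmetric buffer; "
                "reversal is trivially 0 and carries no selectivity information"
            )
        e = _ramp_zero_crossing(tr, smooth_window_mV)
        if e is None:
            logger.warning("ramp %s has no zero crossing in range; excluded", tr.trace_id)
            continue
        per_ramp.append(e)
    if not per_ramp:
        raise EstimationError("no ramp produced a zero crossing")
    arr = np.array(per_ramp)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return ReversalEstimate(
        e_rev_mV=float(arr.mean()),
        sem_mV=sem,
        n_ramps=len(arr),
        per_ramp_mV=tuple(per_ramp),
    )


# ---------------------------------------------------------------------------
# Hille pore-size estimate

@dataclass(frozen=True)
class HilleParams:
    """Inputs to the cylindrical-pore conductance model.

    ``pore_conductivity_factor`` is how many times lower the in-pore
    conductivity is than bulk (rho_pore = rho_bulk * factor).
    """

    conductance_pS: float
    length_min_nm: float
    length_max_nm: float
    rho_bulk_ohm_cm: float
    pore_conductivity_factor: float = 5.0
    variant: str = "cylinder"  # "cylinder" | "cylinder_plus_access"

    def __post_init__(self):
        if min(
            self.conductance_pS,
            self.length_min_nm,
            self.length_max_nm,
            self.rho_bulk_ohm_cm,
            self.pore_conductivity_factor,
        ) <= 0:
            raise ValueError("all HilleParams fields must be positive")
        if self.length_min_nm > self.length_max_nm:
            raise ValueError("length_min_nm must be <= length_max_nm")
        if self.variant not in ("cylinder", "cylinder_plus_access"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class PoreEstimate:
    """Pore diameter range (Angstrom) over the assumed length range."""

    diameter_min_A: float
    diameter_max_A: float
    params: HilleParams


def _diameter_at_length_A(params: HilleParams, length_m: float) -> float:
    g_S = params.conductance_pS * 1e-12
    rho_bulk = params.rho_bulk_ohm_cm * 1e-2  # Ohm m
    rho_pore = rho_bulk * params.pore_conductivity_factor
    if params.variant == "cylinder":
        radius_m = math.sqrt(g_S * rho_pore * length_m / math.pi)
        return 2.0 * radius_m * 1e10

    # cylinder + access resistance: solve 1/g = rho_pore l/(pi r^2) + rho_bulk/(2r)
    target = 1.0 / g_S

    def resid(r: float) -> float:
        return rho_pore * length_m / (math.pi * r * r) + rho_bulk / (2.0 * r) - target

    lo, hi = 1e-13, 1e-6  # 0.001 A .. 10 um brackets any channel pore
    if resid(lo) < 0 or resid(hi) > 0:
        raise ArithmeticError("no positive root bracketed for pore radius")
    # bisection to 1e-4 A on the radius
    tol_m = 1e-4 * 1e-10
    while hi - lo > tol_m:
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) * 1e10  # diameter = 2r


def hille_pore_diameter(params: HilleParams) -> PoreEstimate:
    """Pore diameter range from single-channel conductance.

    Models the pore as an electrolyte-filled cylinder of the given length
    range with in-pore resistivity ``rho_bulk * factor``; the
    ``cylinder_plus_access`` variant adds the bulk access resistance
    rho/(2r).  Diameter grows with assumed length and shrinks with
    conductance.
    """
    d_at_lmin = _diameter_at_length_A(params, params.length_min_nm * 1e-9)
    d_at_lmax = _diameter_at_length_A(params, params.length_max_nm * 1e-9)
    return PoreEstimate(
        diameter_min_A=min(d_at_lmin, d_at_lmax),
        diameter_max_A=max(d_at_lmin, d_at_lmax),
        params=params,
    )
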
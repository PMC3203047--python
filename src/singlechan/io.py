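"""Trace and results file I/O for planar-bilayer recordings.

A trace file is UTF-8 tab-separated text: ``# key=value`` header lines
carrying buffer/protocol metadata, a column-header line
``time_s<TAB>voltage_mv<TAB>current_pa``, then one row per sample.
Units are fixed project-wide: current pA, potential mV, conductance pS,
time s, concentration mM, temperature K.

Stored decimal precision is 6 significant digits for current, 3 for
voltage and 12 for time; round-trip equality is defined at stored
precision.  Sign convention: potential is that of the cis chamber
relative to trans, and positive current is cation flow cis->trans.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = "1"

#: tolerance (mV) for voltage-vs-protocol consistency; matches the stored
#: 3-significant-digit voltage quantization at |V| ~ 100 mV.
VOLTAGE_TOL_MV = 0.5

#: sample spacing must be uniform to within this fraction of trace duration
SPACING_TOL_REL = 1e-6

MANDATORY_KEYS = (
    "format_version",
    "trace_id",
    "sample_rate_hz",
    "temperature_k",
    "ph",
    "kcl_cis_mm",
    "kcl_trans_mm",
    "protocol",
    "v_start_mv",
    "v_end_mv",
    "duration_s",
)


class TraceFormatError(ValueError):
    """File does not conform to the trace format."""


class TraceValidationError(ValueError):
    """Trace content violates a domain invariant."""


@dataclass(frozen=True)
class BufferCondition:
    """Electrolyte on the two sides of the bilayer.

    cis is the sample-addition chamber; concentrations in mM KCl.
    """

    kcl_cis_mM: float
    kcl_trans_mM: float
    temperature_K: float = 293.15
    ph: float = 7.0

    def __post_init__(self):
        if self.kcl_cis_mM <= 0 or self.kcl_trans_mM <= 0:
            raise TraceValidationError("KCl concentrations must be > 0 mM")
        if not (273.15 <= self.temperature_K <= 323.15):
            raise TraceValidationError(
                f"temperature_K={self.temperature_K} outside [273.15, 323.15]"
            )

    @property
    def is_symmetric(self) -> bool:
        return np.isclose(self.kcl_cis_mM, self.kcl_trans_mM)


@dataclass(frozen=True)
class VoltageProtocol:
    """Command-voltage protocol: constant step or linear ramp."""

    kind: str  # "step" | "ramp"
    v_start_mV: float
    v_end_mV: float
    duration_s: float

    def __post_init__(self):
        if self.kind not in ("step", "ramp"):
            raise TraceValidationError(f"unknown protocol kind {self.kind!r}")
        if self.duration_s <= 0:
            raise TraceValidationError("duration_s must be > 0")
        if self.kind == "step" and self.v_start_mV != self.v_end_mV:
            raise TraceValidationError("step protocol requires v_start_mV == v_end_mV")

    def voltage_at(self, t: np.ndarray) -> np.ndarray:
        """Command potential (mV) at times ``t`` (s) from protocol start."""
        t = np.asarray(t, dtype=float)
        if self.kind == "step":
            return np.full_like(t, self.v_start_mV)
        frac = np.clip(t / self.duration_s, 0.0, 1.0)
        return self.v_start_mV + (self.v_end_mV - self.v_start_mV) * frac


@dataclass
class CurrentTrace:
    """Uniformly sampled current recording with protocol and buffer metadata."""

    time_s: np.ndarray
    current_pA: np.ndarray
    voltage_mV: np.ndarray
    sample_rate_Hz: float
    buffer: BufferCondition
    protocol: VoltageProtocol
    trace_id: str

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)

    def __len__(self) -> int:
        return len(self.time_s)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CurrentTrace):
            return NotImplemented
        return (
            self.trace_id == other.trace_id
            and self.sample_rate_Hz == other.sample_rate_Hz
            and self.buffer == other.buffer
            and self.protocol == other.protocol
            and np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.current_pA, other.current_pA)
            and np.array_equal(self.voltage_mV, other.voltage_mV)
        )


def validate_trace(trace: CurrentTrace) -> list[str]:
    """Return a list of violated invariants (empty means valid). Never mutates."""
    problems: list[str] = []
    n = len(trace.time_s)
    if not (len(trace.current_pA) == len(trace.voltage_mV) == n):
        problems.append(
            f"series lengths differ: time={n} current={len(trace.current_pA)} "
            f"voltage={len(trace.voltage_mV)}"
        )
        return problems
    if n == 0:
        problems.append("trace has 0 samples")
        return problems
    for name, arr in (
        ("time_s", trace.time_s),
        ("current_pA", trace.current_pA),
        ("voltage_mV", trace.voltage_mV),
    ):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            problems.append(f"non-finite {name} at index {bad[0]}")
    if problems:
        return problems

    if n >= 2:
        if np.any(np.diff(trace.time_s) <= 0):
            problems.append("sample times not strictly increasing")
        else:
            duration = trace.time_s[-1] - trace.time_s[0]
            dt = duration / (n - 1)
            ideal = trace.time_s[0] + dt * np.arange(n)
            dev = np.max(np.abs(trace.time_s - ideal))
            if dev > SPACING_TOL_REL * max(duration, 1.0 / trace.sample_rate_Hz):
                problems.append(
                    f"sample spacing non-uniform (max deviation {dev:.3g} s)"
                )
            if abs(dt * trace.sample_rate_Hz - 1.0) > 1e-3:
                problems.append(
                    "sample spacing inconsistent with declared sample_rate_hz"
                )

    expected_v = trace.protocol.voltage_at(trace.time_s - trace.time_s[0])
    dev_v = np.max(np.abs(trace.voltage_mV - expected_v))
    if dev_v > VOLTAGE_TOL_MV:
        problems.append(
            f"voltage column inconsistent with {trace.protocol.kind} protocol "
            f"(max deviation {dev_v:.3g} mV)"
        )
    return problems


def _format_row(t: float, v: float, i: float) -> str:
    return f"{t:.12g}\t{v:.3g}\t{i:.6g}"


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """Write a trace to ``path``; the file parses back to an equal trace."""
    if len(trace) == 0:
        raise TraceValidationError("refusing to write empty trace")
    problems = validate_trace(trace)
    if problems:
        raise TraceValidationError("; ".join(problems))
    buf = trace.buffer
    proto = trace.protocol
    header = {
        "format_version": FORMAT_VERSION,
        "trace_id": trace.trace_id,
        "sample_rate_hz": f"{trace.sample_rate_Hz:.12g}",
        "temperature_k": f"{buf.temperature_K:.6g}",
        "ph": f"{buf.ph:.6g}",
        "kcl_cis_mm": f"{buf.kcl_cis_mM:.6g}",
        "kcl_trans_mm": f"{buf.kcl_trans_mM:.6g}",
        "protocol": proto.kind,
        "v_start_mv": f"{proto.v_start_mV:.6g}",
        "v_end_mv": f"{proto.v_end_mV:.6g}",
        "duration_s": f"{proto.duration_s:.12g}",
    }
    lines = [f"# {k}={v}" for k, v in header.items()]
    lines.append("time_s\tvoltage_mv\tcurrent_pa")
    t0 = trace.time_s
    lines.extend(
        _format_row(t0[j], trace.voltage_mV[j], trace.current_pA[j])
        for j in range(len(trace))
    )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_header(raw_lines: list[str], path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(raw_lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            k, _, v = body.partition("=")
            meta[k.strip()] = v.strip()
    else:
        raise TraceFormatError(f"{path}: no data after header")
    missing = [k for k in MANDATORY_KEYS if k not in meta]
    if missing:
        raise TraceFormatError(f"{path}: missing mandatory header key(s): {', '.join(missing)}")
    return meta, i


def read_trace(path: str | Path) -> CurrentTrace:
    """Read and validate a trace file.

    Raises :class:`TraceFormatError` on malformed files (naming the missing
    key or offending line) and :class:`TraceValidationError` when the parsed
    trace violates an invariant.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8").splitlines()
    meta, first_data = _parse_header(raw, path)

    cols = raw[first_data].strip().split("\t")
    if cols != ["time_s", "voltage_mv", "current_pa"]:
        raise TraceFormatError(f"{path}: unexpected column header {cols!r}")
    body = "\n".join(raw[first_data + 1 :])
    try:
        df = pd.read_csv(
            _io.StringIO(body), sep="\t", header=None,
            names=cols, dtype=float,
        )
    except ValueError:
        # slow path: locate the offending cell for the error message
        for off, line in enumerate(raw[first_data + 1 :]):
            if not line.strip():
                continue
            for cell in line.split("\t"):
                try:
                    float(cell)
                except ValueError:
                    raise TraceFormatError(
                        f"{path}: non-numeric cell {cell!r} on line "
                        f"{first_data + 2 + off}"
                    ) from None
        raise TraceFormatError(f"{path}: malformed data section") from None

    try:
        buffer = BufferCondition(
            kcl_cis_mM=float(meta["kcl_cis_mm"]),
            kcl_trans_mM=float(meta["kcl_trans_mm"]),
            temperature_K=float(meta["temperature_k"]),
            ph=float(meta["ph"]),
        )
        protocol = VoltageProtocol(
            kind=meta["protocol"],
            v_start_mV=float(meta["v_start_mv"]),
            v_end_mV=float(meta["v_end_mv"]),
            duration_s=float(meta["duration_s"]),
        )
    except ValueError as exc:
        if isinstance(exc, TraceValidationError):
            raise
        raise TraceFormatError(f"{path}: non-numeric header value ({exc})") from None

    trace = CurrentTrace(
        time_s=df["time_s"].to_numpy(),
        current_pA=df["current_pa"].to_numpy(),
        voltage_mV=df["voltage_mv"].to_numpy(),
        sample_rate_Hz=float(meta["sample_rate_hz"]),
        buffer=buffer,
        protocol=protocol,
        trace_id=meta["trace_id"],
    )
    problems = validate_trace(trace)
    if problems:
        raise TraceValidationError(f"{path}: " + "; ".join(problems))
    return trace


# ---------------------------------------------------------------------------
# generic results tables: TSV with "# key=value" provenance headers

def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a results table as TSV with ``# key=value`` provenance header."""
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in (meta or {}).items()]
    csv = df.to_csv(sep="\t", index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + csv, encoding="utf-8")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV results table; returns (dataframe, provenance metadata)."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8").splitlines()
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(raw):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            k, _, v = body.partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(_io.StringIO("\n".join(raw[i:])), sep="\t")
    return df, meta
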
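"""Pipeline orchestration: simulate -> idealize -> classify -> fit ->
ramp -> ghk -> pore -> swell, driven by one configuration mapping.

Every stage writes a TSV table with a ``# key=value`` provenance header to
the output directory, and the consolidated :class:`AnalysisReport` carries
the in-memory results.  Identical (config, seed) re-runs produce
byte-identical tables: the master seed deterministically derives per-stage
substreams, so adding traces to one stage does not perturb another's
random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conductance import (
    ClassDef,
    ClassFit,
    TotalConductance,
    assign_classes,
    conductance_histogram,
    fit_class_iv,
    fully_open_conductance,
)
from .idealize import (
    IdealizationParams,
    IdealizedTrace,
    events_to_frame,
    extract_gating_events,
    idealize_trace,
)
from .io import BufferCondition, CurrentTrace, read_trace, write_table, write_trace
from .selectivity import (
    HilleParams,
    PoreEstimate,
    ReversalEstimate,
    SelectivityResult,
    find_reversal_potential,
    ghk_permeability_ratio,
    hille_pore_diameter,
)
from .simulate import (
    SwellingParams,
    default_channel_model,
    simulate_ramp_protocol,
    simulate_step_protocol,
    simulate_swelling,
)
from .swelling import SwellingSummary, summarize_swelling

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "idealize", "classify", "histogram",
    "ivfit", "totalg", "ramp", "ghk", "pore", "swell",
)

# fixed offsets so per-stage random substreams are independent of which
# stages are enabled
_STAGE_SEED_OFFSET = {"steps": 1, "ramps": 2, "swelling": 3}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the underlying error."""


@dataclass
class AnalysisReport:
    """Consolidated per-stage results with provenance."""

    outdir: Path
    seed: int
    config_hash: str
    version: str
    tables: dict[str, Path] = field(default_factory=dict)
    total_conductance: TotalConductance | None = None
    class_fits: list[ClassFit] = field(default_factory=list)
    reversal: ReversalEstimate | None = None
    selectivity: SelectivityResult | None = None
    pore: PoreEstimate | None = None
    swelling_summaries: list[SwellingSummary] = field(default_factory=list)
    n_events: int = 0


def _config_hash(config: dict) -> str:
    # outdir is a location, not an analysis parameter: runs of the same
    # analysis into different directories share a hash
    params = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _provenance(config_hash: str, seed: int, stage: str) -> dict:
    return {
        "generator": f"singlechan {__version__}",
        "config_hash": config_hash,
        "seed": seed,
        "stage": stage,
    }


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, _STAGE_SEED_OFFSET[stage]])
    return int(ss.generate_state(1)[0]) % (2**31)


def run_pipeline(config: dict) -> AnalysisReport:
    """Run the enabled stages in dependency order.

    ``config`` keys: ``outdir`` (required), ``seed`` (default 0), ``stages``
    (default: all), plus optional per-stage parameter mappings (``simulate``,
    ``idealize``, ``classify``, ``histogram``, ``ghk``, ``pore``, ``swell``).
    Any stage failure halts the pipeline with the stage name; tables already
    written are preserved.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = tuple(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    chash = _config_hash(config)

    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("singlechan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report = AnalysisReport(outdir=outdir, seed=seed, config_hash=chash, version=__version__)
    status: list[dict] = []

    state: dict = {}
    try:
        for stage in ALL_STAGES:  # fixed dependency order
            if stage not in stages:
                continue
            logger.info("stage %s: start", stage)
            try:
                _STAGE_FUNCS[stage](config, seed, chash, outdir, state, report)
            except Exception as exc:
                status.append({"stage": stage, "status": "failed", "detail": str(exc)})
                _write_status(outdir, status, chash, seed)
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            status.append({"stage": stage, "status": "ok", "detail": ""})
            logger.info("stage %s: done", stage)
    finally:
        _write_status(outdir, status, chash, seed)
        root.removeHandler(handler)
        handler.close()
    return report


def _write_status(outdir: Path, status: list[dict], chash: str, seed: int) -> None:
    df = pd.DataFrame(status, columns=["stage", "status", "detail"])
    write_table(df, outdir / "stage_status.tsv", _provenance(chash, seed, "status"))


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config, seed, chash, outdir, state, report):
    p = config.get("simulate", {})
    model = default_channel_model(noise_sd_pA=float(p.get("noise_sd_pa", 2.0)))
    steps = simulate_step_protocol(
        model,
        duration_s=float(p.get("step_duration_s", 6.0)),
        sample_rate_Hz=float(p.get("sample_rate_hz", 5000.0)),
        seed=_stage_seed(seed, "steps"),
    )
    ramps = simulate_ramp_protocol(
        model,
        n_ramps=int(p.get("n_ramps", 16)),
        duration_s=float(p.get("ramp_duration_s", 4.0)),
        sample_rate_Hz=float(p.get("ramp_sample_rate_hz", 2000.0)),
        seed=_stage_seed(seed, "ramps"),
    )
    trace_dir = outdir / "traces"
    trace_dir.mkdir(exist_ok=True)
    if bool(p.get("write_traces", False)):
        for tr, _ in steps:
            write_trace(tr, trace_dir / f"{tr.trace_id}.tsv")
        for tr in ramps:
            write_trace(tr, trace_dir / f"{tr.trace_id}.tsv")
    sw_seed = _stage_seed(seed, "swelling")
    swells = [
        simulate_swelling(SwellingParams(recovery_rate_per_min=0.02, seed=sw_seed, label="channel")),
        simulate_swelling(SwellingParams(recovery_rate_per_min=0.0, seed=sw_seed + 1, label="protein_free")),
    ]
    state["model"] = model
    state["steps"] = [tr for tr, _ in steps]
    state["ramps"] = ramps
    state["swells"] = swells


def _load_step_traces(config) -> list[CurrentTrace]:
    indir = Path(config["input_dir"])
    traces = [read_trace(f) for f in sorted(indir.glob("*.tsv"))]
    return [t for t in traces if t.protocol.kind == "step"]


def _stage_idealize(config, seed, chash, outdir, state, report):
    p = config.get("idealize", {})
    params = IdealizationParams(
        threshold_k=float(p.get("threshold_k", 4.0)),
        min_dwell_s=float(p.get("min_dwell_ms", 1.0)) / 1000.0,
        e_rev_assumed_mV=float(p.get("e_rev_assumed_mv", 0.0)),
    )
    steps = state.get("steps") or _load_step_traces(config)
    ideals: list[IdealizedTrace] = []
    events = []
    seg_rows = []
    for tr in steps:
        ideal = idealize_trace(tr, params)
        ideals.append(ideal)
        events.extend(extract_gating_events(ideal, tr, params))
        for s, e, m in zip(ideal.starts, ideal.ends, ideal.means_pA):
            seg_rows.append(
                {"trace_id": ideal.trace_id, "voltage_mv": ideal.voltage_mV,
                 "start": int(s), "end": int(e), "mean_pa": m}
            )
    ev_df = events_to_frame(events)
    prov = _provenance(chash, seed, "idealize")
    prov.update(threshold_k=params.threshold_k, min_dwell_s=params.min_dwell_s)
    write_table(ev_df, outdir / "events.tsv", prov)
    write_table(pd.DataFrame(seg_rows), outdir / "segments.tsv", prov)
    report.tables["events"] = outdir / "events.tsv"
    report.tables["segments"] = outdir / "segments.tsv"
    report.n_events = len(ev_df)
    state["ideals"] = ideals
    state["events"] = ev_df


def _stage_classify(config, seed, chash, outdir, state, report):
    p = config.get("classify", {})
    defs = (
        ClassDef("negative", float(p.get("threshold_neg_ps", 220.0))),
        ClassDef("positive", float(p.get("threshold_pos_ps", 180.0))),
    )
    classed = assign_classes(state["events"], defs)
    write_table(classed, outdir / "classed_events.tsv", _provenance(chash, seed, "classify"))
    report.tables["classed_events"] = outdir / "classed_events.tsv"
    state["classed"] = classed


def _stage_histogram(config, seed, chash, outdir, state, report):
    width = float(config.get("histogram", {}).get("bin_width_ps", 25.0))
    rows = []
    for pol in ("negative", "positive"):
        h = conductance_histogram(state["events"], pol, width)
        for lo, hi, c in zip(h.bin_edges_pS[:-1], h.bin_edges_pS[1:], h.counts):
            rows.append({"polarity": pol, "bin_lo_ps": lo, "bin_hi_ps": hi, "count": int(c)})
    write_table(pd.DataFrame(rows), outdir / "histograms.tsv", _provenance(chash, seed, "histogram"))
    report.tables["histograms"] = outdir / "histograms.tsv"


def _stage_ivfit(config, seed, chash, outdir, state, report):
    fits = fit_class_iv(state["classed"])
    df = pd.DataFrame(
        [
            {"polarity": f.polarity, "class_id": f.class_id,
             "slope_ps": f.slope_conductance_pS, "intercept_pa": f.intercept_pA,
             "n_events": f.n_events, "r_squared": f.r_squared}
            for f in fits
        ]
    )
    write_table(df, outdir / "class_fits.tsv", _provenance(chash, seed, "ivfit"))
    report.tables["class_fits"] = outdir / "class_fits.tsv"
    report.class_fits = fits
    state["class_fits"] = fits


def _stage_totalg(config, seed, chash, outdir, state, report):
    tg = fully_open_conductance(state["ideals"])
    df = pd.DataFrame(
        [{"g_neg_ps": tg.g_neg_pS, "g_pos_ps": tg.g_pos_pS,
          "se_neg_ps": tg.se_neg_pS, "se_pos_ps": tg.se_pos_pS,
          "n_neg": tg.n_voltages_per_polarity[0], "n_pos": tg.n_voltages_per_polarity[1]}]
    )
    write_table(df, outdir / "total_conductance.tsv", _provenance(chash, seed, "totalg"))
    report.tables["total_conductance"] = outdir / "total_conductance.tsv"
    report.total_conductance = tg


def _stage_ramp(config, seed, chash, outdir, state, report):
    ramps = state.get("ramps")
    if ramps is None:
        indir = Path(config["input_dir"])
        ramps = [
            t for t in (read_trace(f) for f in sorted(indir.glob("*.tsv")))
            if t.protocol.kind == "ramp"
        ]
    est = find_reversal_potential(ramps)
    df = pd.DataFrame({"ramp_index": range(est.n_ramps), "e_rev_mv": est.per_ramp_mV})
    prov = _provenance(chash, seed, "ramp")
    prov.update(e_rev_mv=f"{est.e_rev_mV:.6g}", sem_mv=f"{est.sem_mV:.6g}", n_ramps=est.n_ramps)
    write_table(df, outdir / "reversal.tsv", prov)
    report.tables["reversal"] = outdir / "reversal.tsv"
    report.reversal = est
    state["reversal"] = est


def _stage_ghk(config, seed, chash, outdir, state, report):
    p = config.get("ghk", {})
    buffer = BufferCondition(
        kcl_cis_mM=float(p.get("cis_mm", 250.0)),
        kcl_trans_mM=float(p.get("trans_mm", 20.0)),
        temperature_K=float(p.get("temperature_k", 293.15)),
    )
    if "e_rev_mv" in p:
        e_rev = float(p["e_rev_mv"])
    elif "reversal" in state:
        e_rev = state["reversal"].e_rev_mV
    else:
        raise ValueError("ghk stage needs e_rev_mv in config or a prior ramp stage")
    sel = ghk_permeability_ratio(e_rev, buffer)
    df = pd.DataFrame(
        [{"e_rev_mv": sel.e_rev_used_mV, "p_k_over_p_cl": sel.permeability_ratio,
          "cis_mm": buffer.kcl_cis_mM, "trans_mm": buffer.kcl_trans_mM,
          "temperature_k": buffer.temperature_K}]
    )
    write_table(df, outdir / "selectivity.tsv", _provenance(chash, seed, "ghk"))
    report.tables["selectivity"] = outdir / "selectivity.tsv"
    report.selectivity = sel


def _stage_pore(config, seed, chash, outdir, state, report):
    p = config.get("pore", {})
    if "g_ps" in p:
        g = float(p["g_ps"])
    elif state.get("class_fits"):
        g = max(f.slope_conductance_pS for f in state["class_fits"])
    else:
        raise ValueError("pore stage needs g_ps in config or a prior ivfit stage")
    rows = []
    pore = None
    for variant in ("cylinder", "cylinder_plus_access"):
        est = hille_pore_diameter(
            HilleParams(
                conductance_pS=g,
                length_min_nm=float(p.get("lmin_nm", 1.0)),
                length_max_nm=float(p.get("lmax_nm", 5.0)),
                rho_bulk_ohm_cm=float(p.get("rho_ohm_cm", 247.5)),
                pore_conductivity_factor=float(p.get("factor", 5.0)),
                variant=variant,
            )
        )
        rows.append(
            {"variant": variant, "g_ps": g,
             "diameter_min_a": est.diameter_min_A, "diameter_max_a": est.diameter_max_A}
        )
        if variant == p.get("variant", "cylinder"):
            pore = est
    write_table(pd.DataFrame(rows), outdir / "pore.tsv", _provenance(chash, seed, "pore"))
    report.tables["pore"] = outdir / "pore.tsv"
    report.pore = pore


def _stage_swell(config, seed, chash, outdir, state, report):
    p = config.get("swell", {})
    thr = p.get("slope_threshold_per_min")
    swells = state.get("swells", [])
    rows = []
    summaries = []
    for tr in swells:
        s = summarize_swelling(tr, None if thr is None else float(thr))
        summaries.append(s)
        rows.append(
            {"label": s.label, "od_baseline": s.od_baseline, "od_min": s.od_min,
             "recovery_slope_per_min": s.recovery_slope_per_min,
             "slope_se_per_min": s.slope_se_per_min, "call": s.call}
        )
    write_table(pd.DataFrame(rows), outdir / "swelling_summary.tsv", _provenance(chash, seed, "swell"))
    report.tables["swelling_summary"] = outdir / "swelling_summary.tsv"
    report.swelling_summaries = summaries


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "idealize": _stage_idealize,
    "classify": _stage_classify,
    "histogram": _stage_histogram,
    "ivfit": _stage_ivfit,
    "totalg": _stage_totalg,
    "ramp": _stage_ramp,
    "ghk": _stage_ghk,
    "pore": _stage_pore,
    "swell": _stage_swell,
}
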
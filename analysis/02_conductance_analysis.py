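#!/usr/bin/env python
"""Idealize the step recordings and analyse gating-event conductances.

Reads the simulated traces from scratch/sim_traces (script 01), idealizes
each constant-voltage recording, extracts gating events, assigns the
two conductance classes per polarity (thresholds 220 pS negative / 180 pS
positive), fits per-class I-V lines, and measures the fully open
conductance per polarity.  Tables go to results/.
"""

from pathlib import Path

from singlechan import run_pipeline

ROOT = Path(__file__).resolve().parent.parent
TRACES = ROOT / "scratch" / "sim_traces"
OUT = ROOT / "results" / "conductance"


def main() -> None:
    if not TRACES.exists():
        raise SystemExit("run analysis/01_simulate_recordings.py first")
    report = run_pipeline(
        {
            "outdir": str(OUT),
            "seed": 1,
            "stages": ["idealize", "classify", "histogram", "ivfit", "totalg"],
            "input_dir": str(TRACES),
        }
    )
    tg = report.total_conductance
    print(f"{report.n_events} gating events from 15 step recordings")
    print(
        f"fully open conductance: {tg.g_neg_pS:.0f} +/- {tg.se_neg_pS:.0f} pS (negative), "
        f"{tg.g_pos_pS:.0f} +/- {tg.se_pos_pS:.0f} pS (positive) -> the channel rectifies"
    )
    for f in report.class_fits:
        print(
            f"class {f.class_id} at {f.polarity} voltages: "
            f"{f.slope_conductance_pS:.0f} pS (n={f.n_events}, r^2={f.r_squared:.3f})"
        )
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
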
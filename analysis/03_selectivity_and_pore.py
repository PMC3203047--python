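#!/usr/bin/env python
"""Reverse potential, GHK selectivity, and Hille pore size.

Pools the zero-current potential over the 16 simulated voltage ramps
(250/20 mM KCl gradient), inverts the GHK voltage equation for the
K+:Cl- permeability ratio, and estimates the pore diameter from the
highest conductance class under both cylinder models.
"""

from pathlib import Path

from singlechan import nernst_potential_mV, run_pipeline
from singlechan.io import read_table

ROOT = Path(__file__).resolve().parent.parent
TRACES = ROOT / "scratch" / "sim_traces"
FITS = ROOT / "results" / "conductance" / "class_fits.tsv"
OUT = ROOT / "results" / "selectivity"


def main() -> None:
    if not TRACES.exists():
        raise SystemExit("run analysis/01_simulate_recordings.py first")
    if not FITS.exists():
        raise SystemExit("run analysis/02_conductance_analysis.py first")
    fits, _ = read_table(FITS)
    g_top = float(fits["slope_ps"].max())
    report = run_pipeline(
        {
            "outdir": str(OUT),
            "seed": 1,
            "stages": ["ramp", "ghk", "pore"],
            "input_dir": str(TRACES),
            "pore": {"g_ps": g_top},
        }
    )
    est = report.reversal
    sel = report.selectivity
    e_nernst = nernst_potential_mV(250.0, 20.0, 1, 293.15)
    print(f"pooled reverse potential: {est.e_rev_mV:.1f} +/- {est.sem_mV:.1f} mV "
          f"over {est.n_ramps} ramps (K+ Nernst bound {e_nernst:.1f} mV)")
    print(f"GHK selectivity: P_K:P_Cl = {sel.permeability_ratio:.1f}:1 -> cation selective")
    pores, _ = read_table(OUT / "pore.tsv")
    for _, row in pores.iterrows():
        print(f"pore diameter ({row['variant']}, g = {row['g_ps']:.0f} pS, l = 1-5 nm): "
              f"{row['diameter_min_a']:.1f} - {row['diameter_max_a']:.1f} A")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
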
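#!/usr/bin/env python
"""Generate the synthetic single-channel dataset.

Simulates the reference rectifying channel (fully open 1260/1010 pS plus
150/350 pS substates, 2 pA noise) under the 15-voltage step protocol in
symmetric 250 mM KCl and 16 alternating voltage ramps under the 250/20 mM
gradient, and writes one trace file per recording.  Trace files are bulky
and regenerable, so they go under scratch/; run this before scripts 02-03.
"""

from pathlib import Path

from singlechan import simulate_ramp_protocol, simulate_step_protocol, write_trace
from singlechan.simulate import default_channel_model

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim_traces"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = default_channel_model(noise_sd_pA=2.0)
    steps = simulate_step_protocol(model, duration_s=6.0, seed=SEED)
    for trace, _ in steps:
        write_trace(trace, OUT / f"{trace.trace_id}.tsv")
    ramps = simulate_ramp_protocol(model, n_ramps=16, seed=SEED)
    for trace in ramps:
        write_trace(trace, OUT / f"{trace.trace_id}.tsv")
    print(f"wrote {len(steps)} step recordings (6 s at 5 kHz, -140..+140 mV)")
    print(f"wrote {len(ramps)} voltage ramps (4 s at 2 kHz, +/-100 mV, 250/20 mM KCl)")
    print(f"traces under {OUT}")


if __name__ == "__main__":
    main()
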
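# singlechan

Analysis toolkit for single-channel electrophysiology of reconstituted
membrane proteins in planar lipid bilayers, built around the
characterization of the chloroplast inner-envelope protein Tic20 as a
rectifying, cation-selective channel. It covers the complete path from a
raw current recording to the biophysical summary numbers:

- **Trace I/O** — a plain-text tab-separated trace format with buffer and
  protocol metadata, validated on read and write.
- **Idealization** — reduction of a noisy constant-voltage recording to a
  piecewise-constant sequence of conductance levels (binary segmentation on
  a sliding-mean-difference statistic with a robust noise estimate), and
  extraction of gating events with conductance g = |ΔI| / |V − E_rev|.
- **Conductance analysis** — event histograms, two conductance classes per
  polarity (thresholds 220 pS at negative, 180 pS at positive potentials),
  per-class I–V line fits, and the fully open conductance per polarity.
- **Selectivity** — zero-current (reversal) potential pooled over voltage
  ramps under a salt gradient, and closed-form inversion of the
  Goldman–Hodgkin–Katz voltage equation for a single binary salt:

      E_rev = (RT/F) · ln[(r·C_cis + C_trans) / (r·C_trans + C_cis)],
      r = P_K / P_Cl

- **Pore size** — Hille-style estimate of the pore diameter from
  single-channel conductance, modelling the pore as an electrolyte-filled
  cylinder (optionally with access resistance ρ/2r) with reduced in-pore
  conductivity.
- **Swelling assay** — summaries of liposome OD₅₀₀ time courses after an
  osmotic salt shock, calling channel presence from the recovery slope.
- **Markov gating simulator** — a continuous-time Markov channel model with
  polarity-dependent conductance levels, GHK-determined reversal, and
  Gaussian recording noise, used to generate statistically faithful
  synthetic recordings so that every analysis stage is testable without
  access to original recordings.

## Worked example

With a measured reverse potential of 37.0 mV under a 250/20 mM KCl
gradient at 20 °C:

```sh
$ singlechan ghk --erev 37.0 --cis 250 --trans 20
P_K:P_Cl = 6.49:1
```

i.e. the channel passes K⁺ about 6.5 times more readily than Cl⁻ — a
cation-selective pore (the K⁺ Nernst potential, 63.8 mV for this gradient,
would be the limit of a perfectly selective channel).

The full synthetic study reproduces every stage. `analysis/` contains
numbered drivers; running them in order prints:

```
$ python analysis/01_simulate_recordings.py
wrote 15 step recordings (6 s at 5 kHz, -140..+140 mV)
wrote 16 voltage ramps (4 s at 2 kHz, +/-100 mV, 250/20 mM KCl)

$ python analysis/02_conductance_analysis.py
302 gating events from 15 step recordings
fully open conductance: 1262 +/- 0 pS (negative), 1012 +/- 1 pS (positive) -> the channel rectifies
class I at negative voltages: 150 pS (n=75, r^2=0.994)
class II at negative voltages: 354 pS (n=58, r^2=0.997)
class I at positive voltages: 152 pS (n=104, r^2=0.996)
class II at positive voltages: 352 pS (n=65, r^2=0.999)

$ python analysis/03_selectivity_and_pore.py
pooled reverse potential: 37.1 +/- 0.0 mV over 16 ramps (K+ Nernst bound 63.8 mV)
GHK selectivity: P_K:P_Cl = 6.6:1 -> cation selective
pore diameter (cylinder, g = 354 pS, l = 1-5 nm): 23.6 - 52.8 A
pore diameter (cylinder_plus_access, g = 354 pS, l = 1-5 nm): 28.4 - 57.4 A

$ python analysis/04_swelling_assay.py
channel: baseline OD 0.100, post-salt minimum 0.079, recovery slope 2.50e-04/min -> channel_positive
protein_free: baseline OD 0.100, post-salt minimum 0.075, recovery slope 2.30e-05/min -> channel_negative
classification accuracy over 200 replicates: 97.5%
```

The simulated channel carries a fully open level of 1260/1010 pS
(negative/positive potential) with substates 150 and 350 pS below it, and
the pipeline recovers those ground-truth values from the noisy traces —
conductances within fractions of a percent, class slopes within a couple
of percent, and the reversal potential within 0.2 mV of the GHK value for
the model's 6.5:1 permeability ratio.

The same stages are available as `singlechan` subcommands
(`simulate`, `idealize`, `classify`, `histogram`, `iv-fit`, `total-g`,
`ramp`, `ghk`, `nernst`, `pore`, `swell`, `run`); `singlechan run
--config pipeline.yaml` executes a configured pipeline end to end with
deterministic seeding and provenance-stamped TSV outputs.

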
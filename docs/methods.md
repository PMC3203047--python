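# Methods

## Scope and units

The package analyses single-channel recordings from planar lipid bilayers
and the accompanying liposome swelling assay. Units are fixed throughout:
current pA, potential mV, conductance pS, time s, concentration mM,
temperature K, optical density dimensionless. The sign convention is that
the potential is that of the cis (sample-addition) chamber relative to
trans, and positive current is cation flow cis→trans; with the
concentrated salt on the cis side, a cation-selective channel therefore
reverses at a positive potential.

## Trace format

Recordings move between stages as UTF-8 tab-separated files: `# key=value`
header lines (trace id, sample rate, buffer composition, temperature, pH,
protocol), one column-header line, then `time_s`, `voltage_mv`,
`current_pa` rows. Stored precision is 6 significant digits for current
(well below recording noise), 3 for voltage, and 12 for time; round-trip
equality is defined at stored precision. Validation checks finite values,
strictly increasing and uniform sample times (maximum deviation from the
affine reconstruction at most 1 ppm of the trace duration), and agreement
of the voltage column with the declared protocol to 0.5 mV — the
quantization bound of 3-significant-digit storage at |V| ≈ 100 mV.

## Channel-gating simulator

The synthetic-data generator is a continuous-time Markov chain over
conductance levels. Level 0 is the fully open state; each level carries two
slope conductances, one per polarity, because the recordings show
rectification as two slope conductances rather than a continuous I–V
curvature. Paths are sampled exactly (exponential dwell with the total
exit rate; next state proportional to its rate), and rendered per sample as

    I = g_level(sign(V − E_rev)) · (V − E_rev) / 1000 + N(0, σ²)

with E_rev from the GHK voltage equation (exactly 0 in symmetric salt) and
white Gaussian noise σ. All stochastic outputs are bit-reproducible given
(inputs, seed); the pipeline derives per-stage and per-trace substreams
from one master seed via `numpy.random.SeedSequence`, so enabling or adding
traces in one stage never perturbs another stage's stream.

The reference model emulates the reported channel: fully open 1260/1010 pS
(negative/positive potential), substates 150 pS and 350 pS below the open
level so that gating-event amplitudes populate both conductance classes on
either side of the 220/180 pS thresholds, ~93% open occupancy, 2 pA noise,
and a 6.5:1 K⁺:Cl⁻ permeability ratio. Gating rates (2/s and 1/s into the
substates, 40/s back) are not constrained by any reported dwell
statistics; they were chosen once to give event counts with good test
power at the protocol durations used here. The study protocol is the
15-voltage step series −140…+140 mV in symmetric 250 mM KCl and 16
alternating ±100 mV ramps under a 250/20 mM gradient. Recording lengths
are scaled for practicality (6 s per step at 5 kHz; 4 s per ramp at
2 kHz), which still yields ~300 resolvable gating events per study.

What the simulator does **not** emulate: capacitive and leak currents,
baseline drift, filter dynamics (noise is white, not filtered), multiple
channels per bilayer, or open-channel noise in excess of baseline noise.
Passing recovery tests on this fixture therefore demonstrates correctness
of the analysis chain under its stated assumptions, not robustness to
every artifact of real bilayer data.

## Idealization

Noise is estimated robustly as MAD(ΔI)/(√2·0.6745) of first differences,
which is insensitive to level steps. Change points are found by binary
segmentation on the difference of adjacent sliding-window means (window =
minimum dwell, default 1 ms): each interval is split at the sample of
maximal |difference| when it exceeds `threshold_k`·σ (default k = 4), and
both halves are re-examined, which keeps closely spaced same-direction
steps separable and makes the detected set grow monotonically as the
threshold is lowered. Segments shorter than the minimum dwell are merged
into the neighbor with the closer mean (minimizing reconstruction error);
boundaries whose mean difference is not significant at the precision of
the two segment means (k·σ·√(1/n₁+1/n₂)) are then dropped, weakest first.
Final level means exclude one sample at each boundary because the sample
containing the transition takes an intermediate value and would attenuate
step amplitudes.

Gating events are adjacent-segment transitions with conductance
|ΔI|·1000/|V − E_rev|. Three resolution rules apply: events within 10 mV
of the assumed reversal are dropped (the conversion divides by the driving
force and becomes ill-conditioned); events with |ΔI| below the raw-sample
detection threshold k·σ are dropped (long segments can make smaller mean
differences statistically significant, but such steps are below the
single-event resolution); and events flanked by a dwell shorter than twice
the minimum dwell are dropped, the usual dead-time rule — their level
means are dominated by transition samples and the amplitude cannot be
measured reliably. Under symmetric salt the assumed reversal is 0 mV.

## Conductance classes and fits

Events are partitioned per polarity into class I (below threshold) and
class II (at or above it); the boundary value itself goes to class II — a
deterministic, documented tie-break. Histograms use left-closed 25 pS bins
from 0. Per-class I–V lines are ordinary least squares of amplitude
(signed by polarity) against command potential with a free intercept,
since nothing forces event amplitudes through the origin; the slope in
pA/mV ×1000 is the class conductance in pS. The fully open conductance is
fit through the origin instead, because the symmetric buffer pins the
reversal at 0 mV: per polarity, the maximal-|current| idealized level at
each voltage gives one (V, I) point, and the slope with its standard error
is reported in pS. Voltages within 10 mV of zero are excluded (no
identifiable open level above noise); at least three usable voltages per
polarity are required.

## Reversal potential and GHK selectivity

Each asymmetric-salt ramp is smoothed with a moving average spanning 5 mV
of command potential (the acquisition smoothing is not otherwise
constrained), zero crossings of current against voltage are located by
linear interpolation, and the median crossing is taken if noise produces
more than one. Crossings are pooled over ramps to a mean and SEM; ramps
without a crossing are excluded with a warning. For a single binary salt
the GHK voltage equation is invertible in closed form:

    r = (ξ·C_cis − C_trans) / (C_cis − ξ·C_trans),  ξ = exp(E_rev·F/RT)

valid only for |E_rev| strictly inside the Nernst bounds of the gradient;
outside it the inversion has no positive solution and a domain error names
the bound. The forward and inverse maps are mutually inverse to machine
precision (property-tested). The default temperature is 293.15 K: the
recording temperature is not otherwise fixed, and 20 °C makes the
(6.5:1, 37.0 mV) pair self-consistent under this equation. Physical
constants are CODATA values, R = 8.314462618 J/(mol·K),
F = 96485.33212 C/mol, pinned for reproducibility.

## Pore-size estimate

The pore is modelled as an electrolyte-filled cylinder of length l with
in-pore resistivity ρ_pore = ρ_bulk × factor (default 5, reflecting
reduced ion mobility in a narrow pore). Two variants are first-class and
always labelled in output:

- `cylinder`: 1/g = ρ_pore·l/(πr²), so d = 2·√(g·ρ_pore·l/π);
- `cylinder_plus_access`: 1/g = ρ_pore·l/(πr²) + ρ_bulk/(2r), adding the
  bulk access (spreading) resistance at both mouths; solved for r by
  bisection to 10⁻⁴ Å on a bracket of 10⁻³–10⁴ Å.

Diameter grows with assumed length and falls with conductance (tested by
finite differences), and the cylinder diameter scales exactly as √g. For
the inputs quoted for this channel (g = 350 pS, l = 1–5 nm,
ρ_bulk = 247.5 Ω·cm, factor 5) these formulas give 23.5–52.5 Å (cylinder)
and 28.2–57.0 Å (with access resistance). The previously published
estimate of 7.8–14.1 Å for the same inputs is **not** reproducible by
either variant — no standard combination of those numbers yields it, and
it is possible the quoted resistivity already contains the 5× correction
or that a different geometric factor was used. The package deliberately
reports its own variant-labelled estimates rather than tuning parameters
toward the published range.

## Swelling assay

The simulated OD₅₀₀ time course reads every minute, holds a baseline
(default 0.1, the typical starting density) until salt addition at 10 min,
drops instantaneously by a fraction (default 0.2, osmotic shrinkage),
then relaxes first-order back toward baseline at `recovery_rate_per_min` —
0 for channel-free liposomes, 0.02/min for channel-positive ones — plus
Gaussian noise spanning a 1.5–3% coefficient of variation, the replicate
spread reported for this assay. The summary takes the pre-salt mean, the
post-salt minimum, and the least-squares slope from the minimum to the end
of the recording. The channel call is positive when the slope exceeds a
threshold; by default the threshold is 3 standard errors of the fitted
slope — a significance rule chosen because the original call was made
visually and no numeric criterion exists. Windows with fewer than three
points after the minimum yield slope 0 and a negative call. Classification
accuracy on paired replicates across the noise band is ≥95% (measured at
200 replicates).

## Numerical and degenerate-input choices

- Exact zeros: the GHK reversal returns 0.0 exactly for symmetric buffers
  or r = 1; the Nernst potential returns 0.0 for equal concentrations.
- Noiseless traces: the detection threshold has an absolute floor of
  ~10⁻⁹ of the signal scale so float rounding cannot fragment a noiseless
  trace; idealization is idempotent on its own reconstruction.
- Absorbing gating states are permitted: the path simply holds the state
  to the end of the recording.
- Sampling coarser than the shortest dwell logs a warning (events alias)
  but is not an error; such events are excluded from amplitude analysis by
  the dead-time rule.
- Empty event selections produce empty (zero-bin) histograms, not errors;
  classes with fewer than two events or no voltage spread are skipped from
  I–V fitting with a warning.

## Problem sizes

Default study sizes — 15 × 6 s steps at 5 kHz, 16 × 4 s ramps at 2 kHz,
a 10⁵ s path for Markov-statistics validation, 200 swelling replicates —
were chosen as the package's own balance of statistical power (hundreds of
gating events, SEMs well inside the stated recovery tolerances) against
run time; the full study completes in seconds.
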
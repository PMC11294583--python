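# Methods

## Model structure and assumptions

The regulon is modelled as seven ODEs for nuclear Ime1 (free and
phosphorylated), cytosolic and nuclear Rim11, the Ime1_P·Ume6 complex C,
its Ume6-phosphorylated form C_P, and free nuclear Ume6.  All
concentrations are in arbitrary fluorescence-equivalent units (AU), time
in hours.  Assumptions inherited from the biology:

* only nuclear Rim11 phosphorylates; the cytosolic pool is an inactive
  reservoir exchanging by first-order import/export;
* Ime1 acts as a scaffold: Ume6 is phosphorylated on the complex, not free;
* C_P activates Ume6 transcription through a Hill term (positive feedback);
* starvation enters only through three logistic signals S1–S3 (floor 0.01,
  growth rate θ = 2 h⁻¹) gating Ime1 synthesis, Rim11 synthesis and Rim11
  nuclear import.

Adaptation is produced by decay terms that read a signal at a delayed time:
d2·Ime1_P·S1(t − k1·τ1) and d4·Rim11_N·S3(t − k2·τ2), a delayed incoherent
feedforward loop.  Because the signals are explicit closed-form functions
of time, these are not true delay differential equations — no history
storage is needed, and evaluation at negative shifted times simply returns
the signal floor.

## Parameters

Rate constants (per hour unless noted): k1=0.85, k2=0.55 (dimensionless
delay multipliers), d1=0.22, d2=3.0, d3=18, d4=0.53, d5=3.0, p1=0.6,
p2=0.4, p3=150, c1=80, c2=35, c3=25 (AU), s1=24, s2=70, a1=1.5 (per AU per
hour), l_cn=0.63, l_nc=0.15, θ=2.  Three quantities have no published
value and are package choices:

* **Hill exponent q = 2** — the smallest exponent giving switch-like
  feedback; exposed in configuration.
* **Signal onsets = 0** — starvation defines t = 0 for all three signals.
* **τ1, τ2** — defined as the nuclear Ime1 and Rim11 peak times.  Rather
  than requiring an external measured time series, the default resolves
  them self-consistently: simulate, read off the peak times, feed them
  back as delays, iterate.  The plain iteration contracts slowly (the
  delay multipliers couple the peaks back to τ almost one-to-one), so each
  cycle applies Steffensen/Aitken extrapolation per component; convergence
  is declared when the accelerated pair reproduces itself within 0.05 h,
  and the result is independent of the starting guess to ~0.1 h.  Peak
  times are refined by parabolic interpolation around the grid argmax so
  the fixed-point map is smooth rather than quantized to the output grid.

## Steady-state closure and the baseline state

Seven basal parameters {a2, b1, b2, b3, l_b, u1, u2} are fixed by
requiring that a chosen pre-starvation state is a steady state when every
signal sits at its floor (0.01).  The system is triangular in these
unknowns and is solved sequentially (u2 from the C_P equation, a2 from C,
u1 from Ime1_P, b1 from Ime1, b2 from Rim11_C, l_b from Rim11_N, b3 from
Ume6); any negative solution is an error naming the offending parameter.
A test cross-checks the sequential solution against a generic 7-d root
finder on the stacked right-hand sides.

The baseline itself is a free modelling choice.  The default,

| ime1 | ime1_p | rim11_c | rim11_n | C | C_P | ume6 |
|-----:|-------:|--------:|--------:|--:|----:|-----:|
| 30   | 4.5    | 32      | 4       | 1 | 0.02| 1    |

was selected (and then frozen) so that the closed model reproduces the
experimentally observed timing hierarchy: most Rim11 cytoplasmic before
starvation (rim11_n ≪ rim11_c), an interior nuclear-Rim11 peak near 5.5 h,
and Ime1/Ume6 peak lags of ≈3 h behind Rim11.  The closure rates the
baseline implies double as kinetic time scales (e.g. u2 sets how fast C_P
tracks Rim11_N), which is why the baseline, not just the printed rate
constants, shapes the transient.  The choice also keeps the per-cell
closure feasible under the generator's lognormal rate jitter: the
dephosphorylation balance u1 = p1·Ime1·Rim11_N/((c1+Ime1)·Ime1_P) − d2·floor
stays positive for p1 multipliers down to ~0.2.

A structural note on the S2+S3 knockout: with the printed constants, q=2
and the default observable map, the knockout's Ume6 response is a
complex-formation bump whose decline is triggered by the same delayed-S1
clock (≈ k1·τ1) that terminates the wild-type Ime1 rise.  Since k1 < 1,
that bump always peaks slightly *before* the wild-type Ume6 peak (which
follows the Ime1 peak at τ1); the knockout's Ume6 response is weaker
(~3.5-fold lower peak) and its rise is delayed, but its argmax is not
later.  Extensive exploration of the baseline space (including randomized
search over all seven components) found no feasible baseline that combines
a later knockout peak with the ≈3 h wild-type lags, so the package
documents the knockout as "weaker and slower-rising" rather than
"later-peaking".

## Observables

Fluorescence-equivalent signals are linear read-outs of the state: the
nuclear Rim11 channel reports free nuclear kinase; the nuclear Ime1 and
Ume6 channels also count the protein held in C and C_P (each complex
carries one copy of each).  Whether imaging channels see complexed
protein is unknowable from intensity data alone; the map is a configurable
3×7 matrix with the above as the documented default.

## Numerics

Integration uses explicit adaptive Runge–Kutta (RK45, rtol 1e-6,
atol 1e-8, max step 0.5 h) sampled on a uniform 0.2 h grid mirroring the
12-min imaging cadence.  Tightening the tolerances 100-fold moves every
sampled value by <1e-4 relative.  Negative excursions beyond −1e-9 AU are
a hard error; smaller ones are floored to zero.  Signal values are clamped
to [floor, 1) to absorb one-ulp rounding.

## Synthetic cohorts

`synth.generate_cohort` emulates a microfluidics experiment: each cell is
meiotic with probability `meiotic_fraction`; meiotic cells run the full
model, non-meiotic cells run it with S2+S3 silenced — reproducing the key
discriminator between fates, high versus basal nuclear Rim11.  Per-cell
variability is unit-mean lognormal multipliers (CV 0.2 by default, a
package choice — cell-to-cell kinetic variability is not quantified in
any reference) applied to the synthesis/transport rates s1, s2, p1, p2,
l_cn only, with the closure re-solved per cell so every cell starts at its
own steady state.  Measurement noise is additive Gaussian (default 2 AU ≈
5% of the wild-type nuclear Rim11 peak); a constant background and a
0.51× red-to-orange bleed-through (the spectral-unmixing coefficient used
for mKOκ/red fluorophore pairs) are added, with the MI-marker channel
serving as the red proxy.

The model contains no division machinery, so MI is generated by a
threshold rule: MI = first crossing of 6 AU by the Ume6 observable plus a
5.25 h offset.  Threshold and offset were calibrated once so the median
gap between MI and the Rim11 peak is 6–7 h, matching the live-cell
observation that the Rim11 peak anticipates MI by about 6 h; meiotic cells
that never cross are reclassified non-meiotic with a warning.  The marker
channel is a 5 AU plateau with a 50 AU sigmoidal step (width 0.15 h) at MI.

What the generator does *not* emulate: segmentation artefacts,
photobleaching, drift, missing frames, non-Gaussian outliers, or any
coupling between noise and intensity.  Passing recovery tests therefore
demonstrates estimator correctness under the stated statistical model, not
robustness to every pathology of real imaging data.

`synth.return_to_growth_cohort` models the starvation-to-rich-medium
switch as plateau-then-exponential decay per compartment with known
half-times (defaults in the analysis drivers: 18 min nuclear, 72 min
cytoplasmic — the regime reported for Rim11).  `planted_timing_cohort`
builds k timing groups by staggering the starvation onset 1 h apart, the
ground-truth partition used to validate clustering.

## Trace analysis

* **MI calling** — argmax of the first difference of the window-3
  median-smoothed marker trace ("highest inflection"), subject to a
  minimum-rise threshold (default 10 AU) that declares non-meiotic cells.
  The smoothing window and threshold substitute for the manual
  confirmation step used with real images.
* **Peak detection** — raw argmax over the 60 frames (Rim11) or 40 frames
  (Ime1/Ume6) before MI; ties break to the earlier frame.
* **Alignment** — traces shifted to put the anchor at relative frame 0;
  frame-wise mean with a 95% normal-approximation CI (mean ± 1.96·SE);
  frames covered by no cell are omitted.
* **Clustering** — Lloyd's k-means under correlation distance
  d = 1 − Pearson r, applied to the first 80 frames after starvation
  onset; the update step is the frame-wise mean of z-scored members (the
  documented centroid dialect), seeding is k-means++ on z-scored traces,
  empty clusters are re-seeded from the worst-fit trace, and the best of
  10 replicates (minimum inertia) is returned.  Mainstream k-means
  implementations assume Euclidean geometry, hence the direct
  implementation.
* **Half-decay** — pre-switch level from the mean of the frames before
  the switch; the crossing is the first frame at or below 50% that stays
  below for 2 consecutive frames (noise guard), refined by linear
  interpolation between the bracketing frames — at a 12-min cadence the
  bare grid would quantize an 18-min half-time to 24 min.
* **Statistics** — squared Pearson correlation for peak/MI timing;
  two-sample Kolmogorov–Smirnov (asymptotic p) with significance at
  P < 0.05.  The asymptotic K–S p-value is conservative below ~100 points
  per sample; calibration tests use n = 100.

## Configuration and seeding

A single YAML file carries model, cohort and analysis blocks plus one
master seed; unknown keys are rejected with their key path.  Per-stage
seeds are derived from the master seed by FNV-style hashing of
(seed, stage name) and kept below 2^31, so stages are independently
reproducible and byte-identical under a fixed master seed.

## Problem sizes

Default study sizes: 24 h simulations on a 121-point grid; recovery
cohorts of 500 cells (mixture), 200 cells (return to growth) and 6×25
cells (planted timing groups); 2000 replicates for the K–S type-I check
and n = 10⁴ pairs for the r² calibration.

## Known limitations

* The model has no division variable; MI exists only through the
  generator's threshold rule.
* Forward simulation only: no parameter inference from data beyond the
  documented steady-state closure.
* The baseline state, q, and the MI threshold/offset are package
  calibrations, not measured quantities; conclusions that depend on them
  (absolute amplitudes, the knockout's exact peak time) should be read
  accordingly.
* Stochastic (SSA/Langevin) and spatial variants are out of scope.
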
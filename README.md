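# meientry

Modelling and single-cell trace analysis of the **Rim11–Ime1–Ume6 regulon**
that gates entry into meiosis in budding yeast.

When *S. cerevisiae* cells starve, the TORC1/PKA nutrient pathways release
three signals: induction of the master regulator Ime1 (S1), induction of the
GSK-3 kinase Rim11 (S2) and nuclear import of Rim11 (S3).  Nuclear Rim11
phosphorylates Ime1; phospho-Ime1 docks onto the promoter factor Ume6, and
Rim11 then phosphorylates Ume6 in the complex, converting it into an
activator of the early meiotic genes.  In live-cell imaging, nuclear Rim11
peaks hours before Ime1 and Ume6, and its peak predicts the timing of the
first meiotic division (MI).

This package is for quantitative biologists who want to (i) simulate that
network, (ii) generate realistic synthetic single-cell fluorescence cohorts
with known ground truth, and (iii) run the trace-quantification pipeline
(MI calling, windowed peak detection, alignment, clustering, half-decay
times) used on such imaging data — and validate it against the generator.

## The model

Seven species — Ime1, Ime1_P, Rim11_C, Rim11_N, the Ime1_P·Ume6 complex C,
its Ume6-phosphorylated form C_P, and free Ume6 — evolve under mass-action /
Michaelis–Menten kinetics driven by three logistic starvation signals
S_i(t) ∈ [0.01, 1) with growth rate θ = 2 h⁻¹:

```
dIme1/dt    = s1·S1 − d1·Ime1 − p1·Ime1·Rim11_N/(c1+Ime1) + u1·Ime1_P + b1
dIme1_P/dt  = p1·Ime1·Rim11_N/(c1+Ime1) − u1·Ime1_P − a1·Ime1_P·Ume6
              + a2·C − d2·Ime1_P·S1(t−k1·τ1)
dRim11_C/dt = s2·S2 − l_cn·S3·Rim11_C + l_nc·Rim11_N − d3·Rim11_C + b2
dRim11_N/dt = l_cn·S3·Rim11_C − l_nc·Rim11_N + l_b·Rim11_C
              − d4·Rim11_N·S3(t−k2·τ2)
dC/dt       = a1·Ime1_P·Ume6 − a2·C − p2·Rim11_N·C/(c2+C) + u2·C_P
dC_P/dt     = p2·Rim11_N·C/(c2+C) − u2·C_P
dUme6/dt    = p3·C_P^q/(c3^q+C_P^q) − d5·Ume6 + b3 − a1·Ime1_P·Ume6 + a2·C
```

The decay terms that read a signal at an earlier time (t − k·τ) implement a
delayed incoherent feedforward loop, producing the adaptive rise-and-fall
of nuclear Rim11 and Ime1.  Seven basal parameters (a2, b1, b2, b3, l_b,
u1, u2) are not free: they are **closed** by requiring a pre-starvation
steady state with all signals at their floor (`model.closure_solve`).  The
delays τ1/τ2 are defined as the Ime1 and Rim11 peak times and are resolved
**self-consistently** against the model's own output
(`model.tau_fixed_point`, a Steffensen-accelerated fixed-point iteration).

## Worked example

```python
from meientry import model

params = model.closure_solve(model.default_parameters())
tau = model.tau_fixed_point(params)
params = params.replace(tau1=tau.tau1, tau2=tau.tau2)
traj = model.simulate(params)                     # 24 h, 12-min sampling
for name in model.OBSERVABLES:
    t = model.peak_time(traj.times, traj.observable(name))
    print(f"{name} peaks at {t:.2f} h")
```

prints

```
rim11 peaks at 5.53 h
ime1 peaks at 8.39 h
ume6 peaks at 9.19 h
```

i.e. nuclear Rim11 peaks ~5.5 h after starvation onset and the nuclear
Ime1 and Ume6 signals lag it by 2.9 h and 3.7 h — the timing hierarchy seen
in imaging.  The numbered drivers under `analysis/` continue the story:

* `01_simulate_model.py` — wild type plus the S1 and S2+S3 signal
  knockouts (the S2+S3 knockout collapses the Ume6 response to ~29% of
  wild type; the S1 knockout caps the Ime1 rise below 2× baseline),
* `02_generate_cohort.py` — a 500-cell synthetic mixture (median
  MI − Rim11-peak gap 6.9 h) and a return-to-growth cohort,
* `03_analyze_traces.py` — full pipeline recovery: 100% of MI calls within
  ±2 frames, Rim11 peak median error 1 frame, half-decay medians 18.8 min
  (nuclear) and 70.9 min (cytoplasmic) against 18/72-min ground truth,
* `04_reproduce.py` — the end-to-end report with pass/fail checks.

A `meientry` console script exposes the same stages
(`simulate`, `generate`, `analyze`, `reproduce`).

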
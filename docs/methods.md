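# Methods

This note documents the model behind `chromostat`, the choices that were
genuinely open when it was built, and what simulation results do and do not
say about the physical system.

## Spectral model

Pigment absorption bands and LED emission lines are unit-height Gaussians
on a fixed 350–750 nm grid at 1 nm (closed interval, trapezoid-rule
integration throughout). Defaults:

| curve   | center (nm) | FWHM (nm) | normalization |
|---------|------------:|----------:|---------------|
| BPR abs |         498 |        90 | unit peak     |
| BR abs  |         568 |       150 | unit peak     |
| blue LED|         465 |        25 | unit area     |
| red LED |         635 |        20 | unit area     |

The activation coefficient is the overlap integral of the two normalized
curves, clipped to [0, 1]: an emission-weighted mean absorbance. With
these defaults the crucial asymmetry of the system holds — blue light
co-activates BR appreciably (coefficient ≈ 0.28) while red light leaves
BPR essentially dark (≈ 0.002). The BR band is deliberately wide: real BR
absorption is broad with a pronounced blue shoulder, and a narrow Gaussian
(e.g. FWHM 100 nm) cannot simultaneously peak at 568 nm and reach blue
wavelengths; 150 nm is the simplest single-Gaussian stand-in for that
shoulder. Photocycle intermediates, quantum-yield wavelength dependence,
and LED thermal shifts are out of scope. Argmax ties break to the shorter
wavelength; overlap integrals demand identical grids (no silent
regridding).

## Plant model

Two well-stirred compartments: the bulk (150 µL) and a single lumped
vesicle lumen (effective 15 µL). State: both pH values plus the five GDH
metabolite pools. Per pump,

    flux = direction · jmax · pool · orientation · drive · backpressure · window

- **drive** = Σ over colors of activation × commanded power.
- **backpressure** = max(0, 1 − ΔpH*/ΔpH_max), with ΔpH* the transmembrane
  gradient along the pump's own direction. The linear form is the simplest
  law with a hard stall; it is not clamped above 1, so a *favorable*
  gradient speeds a pump up (this matters after the enzymatic phase-1 hold,
  which leaves the lumen alkaline and primes BR).
- **window** = product of two logistics in absolute bulk pH,
  midpoints `ph_lo = 5.0` and `ph_hi = 10.2`, width 0.15. The midpoints
  are *not* the quoted evanescence pHs (≈4 and ≈11): evanescence is
  operationalized as "30 min of full illumination move the bulk pH by
  ≤ 0.05 units", which requires near-zero — not half-maximal — activity
  at the quoted starting pHs. With these midpoints the packaged sweep
  reports exactly 4.0 and 11.0.
- **pool**: BPR:BR = 2:1. The ratio is by weight, but both proteins run at
  ≈20 kDa, so the molar ratio is taken equal to it.
- **orientation**: two-thirds of BR inserts C-terminus-out; the minority
  third is modeled as pumping the opposite way with identical kinetics,
  giving the net factor 2f − 1 = 1/3 (config flag `counter_pumping=False`
  makes the minority inert instead). BPR inserts uniformly (factor 1).

Fluxes carry units of pH/s referenced to the washed bulk buffer capacity;
internally they convert to acid equivalents (mM/s) so that
β_out·V_out·ΔpH_out + β_in·V_in·ΔpH_in is conserved exactly for pump and
leak fluxes. The leak relaxes the transmembrane gradient first-order at
`leak_rate` by moving protons down their gradient (conservatively), which
also produces the slow post-maximum pH decline after the enzyme run.

Calibrated defaults (chosen once, against the published closed-loop
behaviors — attainable span above two pH units from a neutral start, more
than one unit between setpoints 5.9/7.2, evanescence at starting pH ≈4
and ≈11, blue changes faster than red, interior staircase setpoints
settled within a 10-minute dwell, and a post-switch turning point in the
enzymatic run):

| parameter | value | units | note |
|---|---|---|---|
| jmax (BR / BPR) | 0.02 / 0.01 | pH/s | per unit pool at full activation |
| ΔpH_max | 2.8 | pH | both pumps |
| ph_lo / ph_hi / width | 5.0 / 10.2 / 0.15 | pH | logistic window |
| β_out | 0.5 | mM/pH | washed saline |
| β_substrate | 1.0 | mM/pH | added while the GDH mix is present |
| β_in | 5.0 | mM/pH | lumen |
| V_out / V_in | 150 / 15 | µL | lumen is an effective lumped volume |
| leak_rate | 2·10⁻⁴ | s⁻¹ | gradient relaxation |

β_in, V_in and the leak are pure calibration artifacts — nothing measured
constrains them individually; only their products and ratios shape the
dynamics. BR's larger intrinsic rate constant compensates its smaller pool
and net orientation factor; BPR still dominates under blue light through
its 2× pool and near-optimal spectral overlap, so acidification remains
the faster direction, as observed.

## Enzyme

GDH is forward-only (the assay tracks only NADH disappearance):
v = vmax · exp(−½((pH−pH_opt)/σ)²) · Π Michaelis–Menten terms, consuming
one bulk proton per turnover. Defaults vmax = 5·10⁻³ mM/s, pH_opt = 8.0,
σ = 0.8, Km = 0.6/1.0/0.2 mM for α-KG/NH₄⁺/NADH. The narrow bell keeps the
reaction idling at pH 6 (v(6)/v(7.4) ≈ 0.06) yet vigorous near neutral,
which is what lets the enzyme overtake the stalling pump after the
setpoint moves to 8.5 and produce the characteristic turning point. In the
standard mix (1.25 mM α-KG, 5 mM NH₄Cl, 2 mM NADH) α-ketoglutarate is
stoichiometrically limiting, so NADH consumption saturates at 1.25 mM and
the absorbance steps shrink toward the end of a run — an emergent feature,
not a fitted one. Product inhibition and the reverse reaction are ignored.

## Controller

Per 1-s tick: read the schedule, measure the electrode (16 ADC reads
averaged; a single raw read has 2 mV ≈ 0.035 pH of noise, oversampling is
the standard logger practice and brings it under 0.01 pH), convert with
the fitted calibration, then

    u = kp·e + ki·integral;   integral += e  (frozen when saturated)

A positive command powers red (raise pH), negative powers blue, magnitudes
clipped to [0, 1]; never both. The command uses the accumulator as carried
*into* the tick, so with gains 5/0.1 a fresh error of +0.1 pH yields red
power exactly 0.5. Anti-windup is conditional integration (the accumulator
freezes whenever the post-update output would saturate in the error's
direction); switching it off (`antiwindup: off`) reproduces the sustained
full-power episodes seen with untuned gains. The integral gain is per
sample — the tick rate is configurable, and a per-second convention is
obtained by scaling ki. No derivative term, no deadband, no hysteresis
between the colors.

## Synthetic data

What the generators emulate, and what they do not:

- **Electrode**: affine V–pH map with i.i.d. Gaussian read noise
  (−57 mV/pH, 2.5 V, 2 mV). No drift, hysteresis, or temperature
  dependence — so long-run calibration stability is *assumed*, and passing
  closed-loop tests say nothing about electrode aging.
- **Vesicle population**: lognormal diameters with analytic mean 130 nm
  (logσ = 0.35) and a configured 20 nM particle concentration. Sizes do
  not feed back into pump kinetics (the plant is lumped), so the
  population model is a characterization target only.
- **Digestion assay**: per-molecule Bernoulli accessibility draws with
  exact Clopper–Pearson 95% intervals; no gel densitometry noise.
- **Assay spectra**: fixed 260-nm matrix band + sloping linear baseline +
  NADH band at 340 nm with height ∝ concentration + Gaussian read noise,
  on 210–750 nm. Matrix and NADH bands have compact support, so at zero
  noise the full pipeline (A260 normalization of the raw spectrum, then
  chord subtraction between exactly 210 and 380 nm, then the value at
  exactly 340 nm) is *exactly* proportional to the injected concentration.
  Real spectra have overlapping bands and scattering tails; the pipeline's
  linearity on synthetic data is a correctness check of the arithmetic,
  not evidence that A260 normalization is unbiased on real matrices.
  Replicate SD is the sample standard deviation (ddof = 1) of the three
  replicates. Sampling-induced pH spikes (aliquot withdrawal) are not
  modeled.

## Numerical choices

- Integrator: fixed-step RK4, dt = 0.1 s (10 substeps per control tick);
  explicit Euler is available and a 1000×-finer Euler run agrees with RK4
  to < 10⁻⁴ pH over 60 s. Metabolite pools are clamped at zero after each
  step with the excess moved to the conjugate pool, preserving
  NADH+NAD⁺ and α-KG+glutamate totals exactly.
- "Plateau" in open-loop sweeps: |dpH/dt| < 10⁻⁴ pH/s sustained 60 s,
  45-min cap. The evanescence sweeps instead use the fixed 30-min
  exposure that defines the limit.
- The background chord is drawn through the curve's values at exactly 210
  and 380 nm (not a fitted regression line): the endpoints then map to
  exactly zero and the operation is testable to machine precision.
  Normalization uses the *raw* spectrum's A260 (the order as performed at
  the bench); the reverse order gives a different result and is rejected
  by a test on purpose.
- Calibration is ordinary least squares of voltage on pH (exact through
  two points); scenario runs calibrate against pH 4/7/10 buffers with
  64-fold averaging.
- All stochastic components draw from per-component generators derived
  from one global seed by a named, CRC-based fan-out; every run artifact
  is byte-reproducible under a fixed seed.

## Scenario conventions

Staircase: setpoints {6.0, 6.25, 6.5, 6.75, 7.0}, 10-min dwells (the
published staircase lists no exact values; this is a stand-in). Range
test: 5.9 → 7.2 → 5.9 with 30-min dwells from a washed pH-6 prep.
Enzymatic run: hold 6.0 for 60 min, then setpoint 8.5 for 90 min; assay
sampling every 15 min by default (10 min via `assay_interval_s: 600` —
both sampling conventions appear in the source material, neither is
assumed correct). The turning point is detected on 60-s binned rates after
the setpoint switch: the first negative-to-positive sign change, else the
first local minimum of the rate. Problem sizes (30-min sweep exposures,
10⁵-vesicle samples, 10⁴-molecule digestion assays) were chosen so every
statistic is far inside its tolerance while a full scenario battery runs
in well under two minutes on one CPU.

## Limitations

The plant is a lumped caricature: one effective lumen, linear
backpressure, no per-vesicle heterogeneity, no osmotic or volume effects,
no photobleaching, no electrode drift. Parameters were calibrated to
reproduce the *published, printed* behaviors of one representative
preparation — they are not measurements, and transferring them to a
different preparation (different lipid, pump ratio, or buffer) would
require re-calibration against that preparation's range test.
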
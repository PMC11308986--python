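# Methods

This note records the models implemented in `forcerheo`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the literature leaves room.

## Data model and units

All internal quantities are strict SI (m, N, Pa, s, Hz); conversions happen
only at I/O boundaries (the UFF-TXT reader converts volt-deflection via the
deflection sensitivity). Piezo position z grows toward the sample during
approach; deflection d is positive in repulsive contact. Indentation is the
kinematic difference δ = (z − z₀) − (d − d₀) about the point of contact
(z₀, d₀), and force is Hooke's law on the deflection change, F = k(d − d₀).

## Contact-point detection

The point of contact is the maximum of the ratio of variances
RoV_i = var(d[i+1..i+N]) / var(d[i−N..i−1]) computed on the raw (unfiltered)
approach deflection. Choices fixed for reproducibility:

- population (1/N) variance; the ratio is unaffected but the convention is
  pinned;
- denominator guard ε_var = 1e-24 m²: windows flatter than this produce
  RoV = 0 rather than an unstable quotient (noiseless synthetic pre-contact
  regions are exactly flat). A consequence is that rescaling the signal far
  below the guard changes the output — scale invariance of the ratio holds
  only while both window variances stay above the guard;
- ties break to the smallest index (earliest contact);
- default window N = 20 samples, overridable everywhere (`--rov-window`).

The detector's accuracy is limited by how quickly the deflection climbs out
of the noise floor: on a very soft sample (≲1 kPa) with sub-nm noise the
onset is buried for several samples and the estimate is biased a few
samples into the contact region. The elastic and viscoelastic fits refine
the contact point as a free parameter precisely for this reason, so the
RoV estimate only needs to be a good starting point. Running RoV on
smoothed deflection would shift the argmax; we do not pre-filter.

## Elastic models

Hertz paraboloid, cone and four-sided pyramid closed forms, a DMT variant
(constant adhesion force added in and out of contact), the Garcia–Garcia
bottom-effect corrected variants, and the Kontomaris deep-indentation
series for spherical tips. Negative-indentation samples contribute only the
force offset (contact clipping), so the contact-point refinement can move
smoothly through them.

Two typographic ambiguities in the source tables were resolved as follows:

- **Pyramid prefactor.** The four-sided pyramid constant is implemented as
  1/√2 (the Bilodeau form) rather than the sometimes-printed 1/2; the two
  are one flag apart (`pyramid_prefactor`), and the module documents the
  choice. Note the viscoelastic geometry coefficient table uses the
  slightly different constant 1.342 (≈1/0.745) for the pyramid; we keep
  each table's own constant so each backend matches its source.
- **Bottom-effect brackets.** The corrections are the canonical
  dimensionless expansions F = F₀ · (1 + a₁x + a₂x² + a₃x³ + a₄x⁴) with
  x = √(Rδ)/h for the paraboloid (a = 1.133, 1.497, 1.469, 0.755) and
  x = δ·tanθ/h shared by cone and pyramid (a = 0.721, 0.650, 0.491, 0.225).
  Dimensional analysis admits only these groupings. The Kontomaris series
  is evaluated with indentation depth as the series variable.

Fits use Levenberg–Marquardt (lmfit) over (E, contact shift, force offset)
with E bounded to [1e-2, 1e9] Pa; non-convergence yields a flagged result
with NaN E, never a silent number. Goodness of fit (R², χ², reduced χ²,
MAE, MSE, RMSE) is computed on the fitted range and exported with every
result row.

## Viscoelastic models

The material is power-law rheology, E(t) = E₀(t/t₀)^(−β), t₀ = 1 s. Forces
follow Ting's hereditary integral with geometry exponent p = 3/2
(paraboloid) or 2 (cone/pyramid) and coefficient C̃ from the standard
geometry table. Two backends:

- **Numerical.** The convolution ∫ E(t−ξ) dδ^p/dξ dξ is evaluated by exact
  product integration: δ^p is piecewise linear on the (uniform) grid, and
  each cell's integral against the weakly singular kernel (t−ξ)^(−β) is
  closed-form, so the singularity at ξ → t costs no accuracy. On retract
  the auxiliary time t₁(t) is the root of ∫_{t₁}^{t} E(t−ξ) δ'(ξ) dξ = 0,
  located by bisection to 1e-3 of a sample interval; the convolution is
  then truncated at t₁. Segments are resampled to 512 uniform points.
- **Analytic.** Constant-velocity closed forms; the paraboloid retract uses
  the Gauss hypergeometric ₂F₁(3/2, β; 5/2; t₁/t) (scipy's implementation,
  exact on [0, 1] including the Gauss value at 1). The cone/pyramid retract
  row was re-derived from the hereditary integral because the printed form
  fails both continuity at t = t_m and lift-off (F → 0 as t₁ → 0); the
  implemented bracket is t^(2−β) − (t−t₁)^(1−β)(t + (1−β)t₁) with
  prefactor 2v_a²E₀t₀^β / (C̃(2−3β+β²)), which satisfies both limits and
  agrees with the numerical backend to <1% on 512-point grids.

The two backends agree to better than 1% for β ∈ {0.1, 0.3} on both
geometries, and both collapse to the Hertz force at β = 0 (for the analytic
branch this is the gamma-function identity 3√π·Γ(1)/(4Γ(5/2)) = 1).

The default cycle fit estimates the contact point (RoV), pre-fits the
elastic model on the approach to seed E₀ and the contact refinement, then
least-squares (E₀, β, contact time, force offset) on force vs time over
the full approach–retract cycle. In the analytic branch the apex time t_m
is also refined within ±10% of the sampled apex: the auxiliary-time map is
sensitive to t_m at the sample-spacing level, and pinning it to the grid
biases E₀ by a few percent. β is bounded to [0, 0.9]: the retract kernels
diverge toward β → 1. Viscous drag is corrected before fitting as
F − b₀·dz/dt, the sign flipping naturally with the piezo velocity.

A caution on intuition: at fixed E₀ the *raw* retract force is not monotone
in β for t ≪ t₀, because the PLR modulus amplifies short-time stiffness;
relaxation is monotone in β only after normalizing by the peak force.

## Microrheology

Per modulation segment: (1) piezo amplitude correction z·A_corr if a glass
calibration is supplied; (2) detrending by a centered rolling mean spanning
exactly one oscillation period (even windows use half-weight endpoints so a
period-long sinusoid averages to zero; one period is discarded at each edge
before demodulation); (3) complex amplitudes by lock-in least-squares
projection at the known drive frequency — robust to non-integer cycle
counts, unlike an FFT bin; (4) transfer function H = F(f)/δ(f); (5) drag
correction H − i·2πf·b₀; (6) contact-model prefactor (paraboloid
(1−ν)/(4√(Rδ₀)), pyramid (1−ν)/(3δ₀tanθ)); (7) piezo phase rotation
G*e^(−iφ_PZT). The working indentation δ₀ is the approach-segment
indentation at the end of the approach, referenced to the RoV contact
point; it is not re-estimated from the modulation segments.

The drag coefficient is extracted as b = Im(H)/(2πf), the unique reading of
a viscous transfer function F_drag = b·(velocity) ⇒ H = i·2πf·b; the
scaled-sphere model b(h) = 6πη a_eff²/(h + h_eff) is fitted over (a_eff,
h_eff) with a linearized 1/b-vs-h initialization, and b(0) = 6πη a_eff²/h_eff.
Default fluid viscosity is water at 25 °C (8.9e-4 Pa·s), overridable.

Ordering of corrections: amplitude → detrend → H → drag → prefactor +
phase, in the order the steps are usually stated. When both piezo-lag and
drag corrections apply, the phase rotation is a rigid rotation of G*
(|G*| preserved); because the measured deflection also enters the
indentation signal, the rotation removes the instrument lag only to first
order in (d-amplitude/δ-amplitude)·φ_PZT. At the default study conditions
(lag τ = 1e-5 s, i.e. 0.7° at 200 Hz; soft-cell moduli ~1–3 kPa) the
residual on G″ stays below 1%; at ten times that lag it would reach several
percent at 200 Hz — a property of the correction itself, not of this
implementation.

The per-cell aggregate is the component-wise geometric mean of G′ and G″
across a cell's curves (a geometric mean of a complex quantity is not
defined; the components are what get plotted and fitted), with log-domain
standard errors. The double power law G′ = A cos(πα/2)f^α + B cos(πβ/2)f^β
(sines for G″) is fitted simultaneously to both components over (A, B, α,
β), exponents bounded to [0, 1.2], terms ordered α ≤ β after the fit. Note
the loss-tangent symbol collision in the field (η for both loss tangent and
fluid viscosity): here they are `loss_tangent` and `eta_fluid`.

## Calibration

The SHO PSD is fitted over (A_white, B, f_R, Q) with f_R initialized at the
maximum bin and Q at 3 (liquid) or 100 (air); a peak below 3× the white
floor is rejected as unresolvable. A_white enters as printed (A_white² in
the PSD). The Sader rectangular formula uses the plan-view *width* (some
texts call the same symbol the thickness — the formula requires width) and
the hydrodynamic function of an oscillating beam: circular-cylinder kernel
1 + 4iK₁(−i√(iRe))/(√(iRe)K₀(−i√(iRe))), Re = ρωb²/(4η), times the
standard rational correction Ω(log₁₀Re) for the rectangular plan view. Its
correctness is certified by property tests (Γ_i > 0 and strictly
decreasing over Re ∈ [1, 1e4]), not by reproducing external tables.

The thermal deflection sensitivity equates the equipartition mean-square
displacement k_BT/k (m²) with the fitted peak's integrated power
πB²f_R/(2Q) (V²); the square-root ratio times the shape correction factor
(defaults 0.90 rectangular, 0.87 V-shaped) is invOLS in m/V. The exact
construction is validated by closed-loop recovery across k ∈ [0.01, 10]
N/m rather than against published instrument tables. Non-rectangular
spring constants must be supplied externally (`external_k`), e.g. from the
GCI virtual instrument, which this package does not call.

## Synthetic data

Generator defaults mirror a typical live-cell protocol: hemispherical
R = 5 µm probe, k = 0.192 N/m, ν = 0.5, 4 µm ramp at 20 µm/s targeting
~500 nm indentation; oscillations of 15 nm amplitude at 0.6, 1, 10, 60,
120 and 200 Hz; drag sweeps at 500 Hz between 0.5 and 2.75 µm separation;
drag-sweep truth a_eff = 30 µm, h_eff = 5 µm in water. Noise is additive
Gaussian on the *deflection* channel (what the instrument digitizes),
specified as a fraction of the peak force and converted through k. All
generators are bit-reproducible under a fixed seed.

The elastic generator solves the implicit force balance k·d = F(δ) per
sample by bisection (monotone, always converges). The Ting generator
prescribes a constant-velocity indentation history and computes force with
the *numerical* backend, so analytic-backend fits of generated data are a
genuine cross-check, never an inversion of the same code. The microrheology
generator synthesizes the oscillatory response from a target G*(f) law
through the contact prefactor, with optional first-order piezo lag
(recorded z leads the actual motion by atan(2πfτ) and over-reads its
amplitude) and drag contamination (+i·2πf·b₀ on the transfer function).

What the generators do **not** emulate: adhesion hysteresis, thermal drift
beyond a linear slope, cell-population heterogeneity beyond lognormal
scale scatter, tilt/virtual-deflection artifacts, finite piezo-turnaround
dynamics, or multi-eigenmode thermal spectra. Passing closed-loop tests
therefore demonstrates correctness of the estimators under the stated
physics, not robustness to every artifact of real instruments.

## Problem sizes

The validation suite runs entirely on synthetic data at desk scale:
512-point grids for backend comparisons, 200-seed Monte Carlo for the
Hertz and Ting noise-recovery studies, 100 seeds for the SHO and drag
studies, and an emulated population study of 20 cells × 16 curves with
10 000 bootstrap resamples for the median standard error. The acceptance
script reports each quantity together with the problem size it used.

## Known limitations

- Sample thickness for bottom-effect models must be supplied by the user;
  there is no automatic thickness determination.
- The analytic viscoelastic backend assumes constant approach/retract
  speeds; use the numerical backend for arbitrary ramps.
- The piezo-lag correction is first-order (see above).
- Only the rectangular Sader formula is implemented; V-shaped cantilevers
  get the shape-specific invOLS correction factor but need an external k.
- No parsers for proprietary binary formats; curves enter via UFF-TXT or
  programmatically.
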
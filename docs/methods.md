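# Methods

## The measurement problem

During the isovolumic relaxation time (IVRT, aortic valve closure → mitral
valve opening) ventricular volume is constant and wall deformation is
governed almost entirely by active relaxation. In mice the window is short
(~15–25 ms at 400–450 bpm), so extracting anything meaningful from it puts
hard constraints on frame rate, smoothing and differentiation. The package
operationalises "isovolumic relaxation strain imaging" as: filter the raw
strain export once, differentiate numerically, snap the [AVC, MVO] window
onto the sample grid, and read off four extrema per signal — max/min value
and max/min acceleration — signed and absolute, per segment and averaged
across segments. The single most sensitive index is the minimal
acceleration of the radial strain rate (min d(SR)/dt within IVRT): it
captures how abruptly the wall decelerates as relaxation begins, and it
shrinks in magnitude when relaxation slows.

## Signal processing choices

* **Filter.** Low-pass Butterworth, cutoff 20 Hz, order 2 — the smoothing
  instrument software applies to raw strain. Only raw strain is filtered;
  derivatives are not re-filtered. Default application is zero-phase
  (forward–backward), so the valve-event alignment of windows is not
  corrupted by group delay; a causal single-pass mode exists for strict
  replication of on-device behaviour. Per pass the magnitude follows
  |H(f)| = (1+(f/f_c)^{2·order})^{-1/2} up to bilinear-transform warping,
  which is negligible when f ≪ f_s/2.
* **Differentiation.** Second-order central differences
  (`np.gradient`, second-order one-sided stencils at the ends). Robust at
  window edges and matches what generic strain software does; error is
  O(Δt²). Acceleration of a signal means "the second derivative of the
  underlying deformation": two derivatives of strain, one of strain rate
  or velocity.
* **Windowing.** Closed interval with nearest-sample snapping. The IVRT is
  so short that dropping boundary samples visibly biases extrema. If fewer
  than three sample instants fall inside a window the frame rate cannot
  resolve the phase and the operation fails rather than degrade silently
  (at 100 Hz an 18 ms IVRT holds two samples; at 1000 Hz, nineteen).
  Derivatives are computed on the full trace *before* windowing so the
  stencils never straddle a cut.
* **Averages.** "Segment-averaged" metrics are the unweighted mean of
  per-segment values, not the metric of the segment-averaged curve. The
  two differ whenever segment extrema occur at different instants; the
  per-segment form keeps segments exchangeable and matches per-segment
  reporting conventions. This is an interpretation choice and is exposed as
  such.
* **Weiss tau.** Ordinary least squares of ln P on t over [AVC, MVO];
  τ = −1/slope. The intercept absorbs pressure scale, so calibration
  errors that rescale P leave τ untouched. dP/dt extrema come from the
  same central-difference derivative over the whole cycle.
* **Conventional ratios.** FS = 100·(LVIDd−LVIDs)/LVIDd, LV volumes by
  Teichholz V = 7.0/(2.4+D)·D³, EF from the volumes, E/A and E/E′
  elementwise.

## The simulator

The simulator generates what the pipeline needs to be tested against:
single cardiac cycles with a distinct IVRT phase, segment heterogeneity,
and a controllable active-relaxation constant; and longitudinal sham/TAC
cohorts built from those cycles.

One cycle of length T = 60/HR (default HR 420 bpm, frame rate 1000 Hz,
IVRT 18 ms ≈ 18 samples) is, for radial strain of one segment:

* cosine ramp 0 → peak (default 25%) over systole, ending at the
  relaxation onset t₀ placed 3 ms before AVC — relaxation begins in late
  systole, so the curve is already decaying when the window opens;
* from t₀, strain = peak·exp(−g(u)/τ) with g(u) = u − b·(1−e^{−u/b}),
  b = 5 ms. g(0) = g′(0) = 0 gives a smooth onset; g → u − b makes the
  decay asymptotically exponential with time constant τ through the IVRT
  and E-wave. The smooth onset matters: the headline metric is a second
  derivative, and a C¹-only joint at the window edge would put a
  second-derivative discontinuity exactly where the minimum is read,
  making the metric grid-dependent;
* a raised-cosine taper (applied only after MVO) brings the decay to zero
  by the end of the E-wave, diastasis sits at zero, and a small sin²
  atrial-kick bump (6% of peak) returns to zero at the cycle end, making
  the curve C¹-periodic;
* longitudinal strain mirrors the radial shape in sign at 0.6× amplitude;
  endocardial gain 1.0 > epicardial 0.8; six multiplicative segment gains
  (0.92–1.10) model heterogeneity; additive Gaussian noise on strain
  (default σ = 0.5 % strain, a plausible speckle-tracking noise floor);
* pressure: cosine rise to 90 mmHg, fall to 60 mmHg at AVC, exact
  P = P_avc·e^{−u/τ} during IVRT (so the Weiss method recovers τ),
  raised-cosine settling to an 8 mmHg end-diastolic pressure.

With this kinematics |min accel of radial SR| ≈ peak/(τ·b)-scaled at the
window onset, hence strictly decreasing in τ over the physiological grid
(verified against a 10 kHz dense evaluation; the 1000 Hz pipeline agrees
within ~2–3%).

**Cohorts.** TAC is modelled purely as τ prolongation (default 24 ms vs
sham 12 ms; an optional per-day slope and a peak-strain reduction flag
allow late-stage systolic decline). Each animal draws a Gaussian offset on
τ (SD 1 ms) held constant across days — the between-animal random
intercept. No quantitative relaxation kinetics for TAC mice are available
to calibrate against, so these values are physiologically plausible
stand-ins; the separate response-level generator
(`simulate_linear_cohort`) produces cohort tables directly from the linear
mixed model for statistical calibration, with defaults (group effect
−0.14, day slope −0.004, intercept SD 0.02, residual SD 0.02, n = 10/group,
days 1–14) on the scale of the headline metric's reported effects.

**What passing tests do and do not show.** The simulator produces smooth,
cycle-locked, single-beat traces with exactly known ground truth. Real
exports add respiration gating artefacts, tracking drop-outs, beat-to-beat
variability of valve timings, and correlated (not white) measurement
noise. Tests against the simulator therefore validate the *pipeline
mathematics* — windowing, filtering, differentiation, model fitting — not
the robustness of speckle tracking itself, which is out of scope.

## Statistics

* **Welch t-test** with Welch–Satterthwaite df and mean-difference CI;
  degenerate zero-variance input falls back to t=0, p=1 (equal means).
* **Power analysis.** Cohen's d from summary statistics with the equal-n
  pooled SD √((s₁²+s₂²)/2); required n per group is the smallest n whose
  exact noncentral-t power (ncp = d·√(n/2), df = 2n−2) reaches the target.
  For the pilot values (0.022±0.017 vs 0.056±0.023, d = 1.68) the exact
  two-tailed computation requires n = 7 per group (power 0.746 at n = 6);
  n = 6 is the one-tailed answer (power 0.856 at 6, 0.782 at 5). Both are
  reported; the two-tailed result is what the stated design implies.
* **Linear mixed model.** value ~ group + day + (1 | animal), REML. The
  profiled likelihood is one-dimensional in λ = σ²_b/σ²_e (random-intercept
  structure makes every per-animal block I + λJ analytically invertible),
  optimised by bounded scalar search. Satterthwaite df per coefficient:
  df = 2·f²/(gᵀAg) with f = Var(β̂_j), g its finite-difference gradient in
  (σ²_b, σ²_e), and A the inverse observed REML information (finite-
  difference Hessian). Wald-t CIs use the same df. Singular fits
  (σ̂²_b → 0) are flagged, not fatal, and fixed effects then equal OLS; an
  ill-conditioned variance Hessian falls back to residual df with a logged
  warning. A perfectly linear, noise-free table short-circuits to the exact
  solution with zero variance components. The fit is cross-checked against
  lme4 + lmerTest (estimates to ~1e-6, df to ~1e-3) on a frozen fixture,
  and 95% CI coverage of the group effect is 94–97% over 500 simulated
  cohorts.
* **Multiplicity.** Benjamini–Hochberg step-up across all panel metrics
  of one analysis run as a single family (the family definition is
  configurable by running panels separately).
* **Agreement.** ICC fixed to the two-way random, absolute-agreement,
  single-measure form ICC(A,1) — the variant is an assumption, stated here.
  Bland–Altman bias = mean(x−y) with 1.96·SD limits.

## Numerical conventions and degenerate inputs

Time is seconds internally everywhere; millisecond files convert at read
time. Uniform grids are enforced at relative jitter < 1e-6; NaN runs of up
to 3 samples are linearly interpolated, longer runs are rejected
(filtering and differentiation need a sound grid, and longer gaps are not
recoverable at these time scales). Trace columns follow the grammar
`<direction>_<layer>_seg<k>_<kind>`, which is total over everything the
simulator emits. Output tables are tab-separated with 10 significant
digits; trace CSVs round-trip exactly (17 significant digits, round-trip
float parsing).

## Problem sizes

The heavier checks run at deliberately chosen sizes: 100 trace-level
cohort replicates (10 animals/group × 14 days at 1000 Hz) for the Welch
detection rate, 500 response-level cohorts for LMM coverage, 2000
replicates for empirical size/power of the Welch test, and a 6-point τ
grid against a 10 kHz dense oracle. These sizes give binomial/Monte-Carlo
error well inside the asserted tolerances while keeping a full run in the
minutes range on one CPU.

## Known limitations

* The simulator's TAC kinetics are stand-ins, not fitted to animal data;
  absolute metric values are in simulator units (%/s² of percent strain)
  and are not comparable to instrument exports with unknown unit
  conventions.
* The acceleration-of-strain-rate reading (one derivative of SR) follows
  the convention that "acceleration" always means the deformation's second
  derivative; exports that pre-compute accelerations differently should be
  imported as `acceleration` traces directly.
* The LMM implements the random-intercept structure only (the structure
  the longitudinal design implies); random slopes are out of scope.
* Whether absolute or signed extrema enter group statistics is a genuine
  reporting ambiguity; both are always computed and stored, and the panel
  defaults to absolute values.
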
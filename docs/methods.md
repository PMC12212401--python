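# Methods

## Models

Tissue kinetics follow the two standard compartment models of dynamic PET.
For a reversible tracer the 1-tissue model

    dC_f/dt = K1 Cp(t - Δ) - k2 C_f,      C(t) = (1 - vB) C_f + vB Cb(t - Δ)

with `K1` (mL/min/cm³) the plasma-to-tissue transfer rate, `k2` (1/min) the
efflux rate, `vB` the fractional blood volume and `Δ` (min) the
input-to-tissue delay.  The macro-parameter of interest is the volume of
distribution `V_T = K1/k2`.  For an irreversibly trapped tracer the
2-tissue model with the dephosphorylation rate fixed at zero adds a trapped
compartment fed at `k3` (1/min); its macro-parameter is the net influx rate
`K_i = K1 k3/(k2 + k3)`.  The whole-blood curve serves as both the driving
input `Cp` and the blood-signal term `Cb`: the emulated workflow uses an
image-derived aortic input without plasma separation or metabolite
correction, and the package deliberately mirrors that (a known limitation,
not an omission).

All model evaluation reduces to convolutions of the input with exponential
kernels.  These are computed exactly for piecewise-linear inputs by
closed-form integration over each segment (a recursion `y_{i+1} = y_i
e^{-k h_i} + β_i`, vectorised in overflow-safe blocks), rather than by FFT
or fixed-step quadrature, so frame boundaries introduce no grid artefacts.
Smooth analytic inputs are sampled on a graded grid (5 ms near the bolus,
coarsening to 0.1 min) before the same exact piecewise-linear convolution;
against a brute-force 0.001-min convolution the evaluators agree to better
than 0.1% over the physiological parameter range.

## Framed data and decay

A `TimeActivityCurve` carries an explicit decay-correction state: applying
or removing decay correction flips a flag and records the reference time,
so double application is a type error rather than a silent bug.  Correction
uses the frame mid-time factor `exp(±λ (t_mid - t_ref))`, the common
scanner convention.  The synthetic generator, by contrast, applies decay to
the continuous signal *before* frame averaging (the exact frame-integral
form); the small difference between the two conventions is part of what the
recovery studies absorb.

Scanners report frame averages, not point samples.  Two consequences are
handled explicitly:

* When a framed blood curve must become a continuous input for fitting or
  projection, the package solves a small linear system for piecewise-linear
  knot values whose frame averages reproduce the measured values
  (`average_preserving_interpolant`), instead of interpolating through
  mid-times.  This removes most of the bolus-peak binning bias; on
  noiseless data it cuts the `K_i` recovery error from ~0.5% to <0.05%.
* The triexponential blood-tail fit compares analytic frame averages of
  `Σ A_i e^{-L_i(t - t_0)}` with the measured frame values, which makes the
  projection beyond the measured window accurate to ~1e-7 relative on
  noiseless data instead of a few percent.

## Estimation

`fit_compartment` is bounded nonlinear weighted least squares
(`scipy.optimize.least_squares`) over the micro-parameters, repeated on a
discrete delay grid with the best grid point winning.  `fit_separable`
exploits the model structure: for fixed `k2` (1TCM) or `θ = k2 + k3`
(2TCM-irrev) the remaining parameters are linear and solved by bounded
linear least squares (non-negativity enforces physical parameters; the
blood fraction is capped), so the nonlinear search is a one-dimensional
log-grid with optional bounded refinement.  The 2TCM coefficient map is
`K1 = (α1+α2)/(1-vB)`, `k3 = θ α1/(α1+α2)`, `k2 = θ α2/(α1+α2)`,
`K_i = α1/(1-vB)`.

Defaults: weights `w_i = Δt_i e^{-λ t_i}` (approximate inverse variance for
decay-corrected count data; uniform available); delay grid −1 to +2 min in
0.1-min steps; bounds `K1 ∈ [0,5]`, `k2, k3 ∈ [0,5]` /min, `vB ∈ [0,0.5]`;
initial values `K1 = 0.1`, `k2 = 0.1`, `k3 = 0.01`, `vB = 0.05`; 48-point
nonlinear grid.  Standard errors come from the Gauss-Newton curvature at
the optimum.  The triexponential fit uses 8 multistart rate triples
(log-spaced, seeded) with amplitudes solved by non-negative least squares
inside the residual (variable projection), and needs at least 7 post-peak
frames.  Monte-Carlo and grid studies in the tests and acceptance script
fix the delay grid to {0} because the generator applies no delay; the full
grid is exercised by a dedicated delay-recovery test.

Graphical estimators use trapezoidal cumulative integrals over frame
mid-times with a virtual zero anchor at t = 0 and ordinary least squares on
the late-time points.  `t*` defaults to 15 min (Logan) and 20 min (Patlak);
`select_tstar` alternatively picks the earliest start time whose points all
lie within a relative tolerance of the refit line.  The blood-volume term
is not subtracted before regression, so on tissue with `vB > 0` the
graphical slope estimates `(1-vB)` times the macro-parameter — matching
common practice and documented rather than hidden.  Closed-form checks
therefore use `vB = 0`.

## Dual-tracer pipeline

Frames are assigned to the two segments by mid-time, with a half-open
convention at the second injection (a frame starting exactly at the
injection belongs to the second segment); the generator guarantees a frame
boundary there, and real data straddlers are dropped with a warning.  The
correction operates in the decay-uncorrected (measured) domain, following
the order: remove correction → fit/project → subtract → reapply
correction.  The first segment is referenced to the first injection and the
corrected second segment to the second injection, which makes each tracer's
analysis self-consistent.  Negative post-subtraction values are clipped to
zero and counted in the report.  Percent differences are always quoted
relative to the measured/uncorrected quantity.

First-tracer tissue residuals are projected through the 1TCM fitted to the
decay-uncorrected first-segment data.  This is exact self-consistently: if
the corrected concentrations obey a 1TCM, the uncorrected ones obey a 1TCM
with `k2 → k2 + λ`, so fitting and forward-projecting in the measured
domain introduces no model error.

The joint simultaneous fit avoids that domain subtlety by construction:
each tracer's input component is decay-corrected to its own injection,
drives the compartment model with decay-free rate constants, and the model
output is decay-weighted back to the measured domain before comparison.
Per region the only nonlinear parameters are `k2` of the first tracer and
`θ` of the second (16×16 coarse log-grid, Nelder-Mead polish); the two
uptake amplitudes, the trapped amplitude and a shared blood fraction are
linear.  The joint fit does not search a delay: the input components
already carry the measured blood timing, and the subtraction route
estimates delay through its own options.

## Synthetic data

The generator emulates the measurement chain of the staggered protocol:

* **Input function**: per tracer, activity-proportional bolus
  `(1 - e^{-τ/0.3}) Σ a_i e^{-L_i τ}` with per-MBq amplitudes
  (0.18, 0.05, 0.035) kBq/mL and rates (3.0, 0.3, 0.012) /min — peak ~0.7
  min post-injection, blood SUV ≈ 2 at 25 min, and a tail that is exactly
  triexponential beyond a few minutes so the correction's projection model
  is well-specified in form (its *parameters* are still estimated from
  framed first-segment data only).
* **Tissue curves**: frame-averaged forward models with physical decay, so
  all generated data are decay-uncorrected, as off a scanner.  The default
  tumor truth is `V_T = 0.6` (K1 0.12, k2 0.2, vB 0.05) for the reversible
  tracer and `K_i ≈ 0.01525` (K1 0.10, k2 0.10, k3 0.018, vB 0.05) for the
  trapped one; five more organs (gray matter, kidney, myocardium, muscle,
  spleen) carry literature-plausible placeholder kinetics.
* **Protocol constants**: 41 MBq at t = 0, 394 MBq at t = 29 min, 93.5 kg
  (dual study); 263 MBq, 70 min, 84.5 kg (single-tracer design study);
  18F half-life 109.77 min.
* **Framing**: 12×10 s, 6×30 s, 5×60 s, 4×4 min and a closing 3-min frame
  to 29 min (4-min blocks cannot tile 29 min exactly); the second segment
  restarts fine framing at the injection and ends with 5-min frames at
  89 min.  The single-tracer schedule runs 4-min frames to 70 min.
* **Noise**: zero-mean Gaussian on the decay-uncorrected values with
  variance `noise_scale · C_i / Δt_i`, clipped at zero — a large-count
  approximation of Poisson statistics.  The default
  `noise_scale = 0.01` gives late tumor frames a few-percent coefficient of
  variation at the 41-MBq level and visibly unstable `V_T` at
  emulated quarter doses, the regime the protocol-design study probes.
* **Dose thinning**: subsampling to a fraction f keeps the renormalised
  expectation unchanged and scales the count variance by 1/f, realised by
  adding the variance increment to the existing noise; injected-activity
  metadata scale by f.  Null-tracer studies (for degenerate tests) are
  produced by zero-amplitude input shapes rather than zero injected
  activity, which stays positive by type invariant.

What the generator does **not** emulate: image reconstruction and its
correlated noise, scanner-specific sensitivity, dispersion of the input
function, plasma metabolites, patient motion.  Passing recovery tests on
these synthetics therefore validates the estimation and correction
machinery, not the full physics of a scanner; absolute error levels on real
data will differ.

## Problem sizes

The recovery study uses 50 noisy replicates of a single-region (tumor)
study; the stability grid uses 6 emulated dose levels plus the full-dose
reference × 5 durations × 25 replicates; the convolution oracle uses 100
random parameter draws.  These sizes give Monte-Carlo error comfortably
below the effect sizes being tested while keeping a full run of the test
suite and acceptance script to a couple of minutes.

## Known limitations

* Identical isotopes are assumed in spirit but not enforced: each injection
  carries its own half-life, yet mixed-isotope studies are untested.
* The graphical estimators inherit the `(1-vB)` scale factor and the Logan
  plot's documented low bias under tissue noise.
* The joint fit shares one blood fraction between the two tracers' models
  (they describe the same region) and estimates no delay.
* Clipping negative corrected values at zero slightly biases very noisy
  curves upward; clip counts are reported so the effect is visible.
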
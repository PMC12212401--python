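# dualtracer

Kinetic analysis of sequential same-session dual-tracer dynamic PET.

High-sensitivity long-axial-field-of-view PET scanners make it practical to
image two 18F-labelled tracers in a single session: a first tracer at a low
injected activity, followed ~30 minutes later by a second tracer at roughly
ten times the activity, whose signal overwhelms the residual of the first.
Because both tracers share the isotope, the second segment of the scan still
contains first-tracer signal that must be projected forward and subtracted
before the second tracer can be quantified.  This package implements that
workflow end to end for the tracer pair this protocol was designed around —
a glutamine analogue ([18F]FGln, reversible kinetics) followed by [18F]FDG
(irreversible trapping) — together with the synthetic-data machinery needed
to validate it against known ground truth.

It is aimed at researchers developing or evaluating multi-tracer dynamic
PET protocols who work from region-level time-activity curves (TACs) rather
than raw images.

## Models and estimators

* **1-tissue compartment model** for the reversible tracer:
  `C(t) = (1-vB) K1 e^(-k2 t) ⊗ Cp(t-Δ) + vB Cb(t-Δ)`, with macro-parameter
  the volume of distribution `V_T = K1/k2` (mL/cm³).
* **2-tissue irreversible compartment model** (`k4 = 0`) for the trapped
  tracer, with macro-parameter the net influx rate
  `K_i = K1 k3/(k2+k3)` (mL/min/cm³).
* **Graphical estimators**: Logan plot (slope → `V_T`) and Patlak plot
  (slope → `K_i`), with automatic `t*` selection.
* **Two fitting routes**: classical bounded Levenberg-Marquardt over all
  micro-parameters, and a separable-parameter-space formulation in which
  the linear coefficients (uptake amplitudes, blood fraction) are solved in
  closed form so the nonlinear search is one-dimensional.
* **Residual-signal correction**: decay correction is removed, the
  first-tracer blood curve is fit by a triexponential and projected over
  the second segment, first-tracer tissue curves are projected through
  their fitted compartment models, both are subtracted, and decay
  correction is reapplied referenced to the second injection.
* **Joint simultaneous fit**: both tracers' models are fit in one weighted
  least-squares problem over the full schedule, with only two nonlinear
  rate parameters per region.
* **Protocol design**: dose-thinning and scan-truncation grids map the
  stability of `V_T` against emulated injected activity and scan duration.

The whole-blood image-derived input function serves as both `Cp` and `Cb`
(no plasma separation or metabolite correction), matching the clinical
workflow the package emulates.

## Worked example

Simulate the default study — 41 MBq of the reversible tracer at t = 0
imaged for 29 min, then 394 MBq of the irreversible tracer for another
60 min, 93.5-kg subject, count-limited noise — and run the full analysis:

```python
from dualtracer import (AnalysisConfig, FitOptions, default_dual_truth,
                        run_dual_tracer_analysis, simulate_dual_tracer_study)

truth = default_dual_truth(seed=7, regions=("tumor",))
study, _ = simulate_dual_tracer_study(truth)
config = AnalysisConfig(options=FitOptions(delay_grid=(0.0,)))
report = run_dual_tracer_analysis(study, config)["regions"]["tumor"]
```

which prints (via the formatting in the repository's examples):

```text
V_T (1TCM):        0.605 mL/cm^3
V_T (Logan):       0.633 mL/cm^3
K_i uncorrected:   0.01451 mL/min/cm^3
K_i corrected:     0.01520 mL/min/cm^3
K_i (Patlak, corr):0.01493 mL/min/cm^3
K_i (joint fit):   0.01524 mL/min/cm^3
residual in final frame: 2.5 %
```

The generating truth here is `V_T = 0.6` and `K_i = 0.01525`: the
compartment fit recovers both within a few percent at this noise level; the
uncorrected `K_i` is biased low because the residual first-tracer signal
contaminates both the blood curve and the tissue curve, and the correction
removes most of that bias.  The joint simultaneous fit agrees with the
subtraction pipeline.  The residual first-tracer contribution to the final
frame is a few percent — small enough that a delayed static image of the
second tracer remains quantitatively usable.

A command-line interface wraps the same machinery:

```sh
dualtracer simulate --seed 1 --out tacs.csv --study-out study.yaml
dualtracer run --study study.yaml --tacs tacs.csv --out report.json
dualtracer stability --seed 0 --reps 25 --out stability.csv
```

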
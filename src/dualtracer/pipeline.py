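"""Sequential dual-tracer analysis: residual correction and joint fitting.

A dual-tracer study injects a reversible tracer at a low activity, images
it for a first segment, then injects an irreversible tracer of the same
isotope at a ~10x activity and continues imaging.  Because both tracers
share the isotope, the second segment contains residual first-tracer
signal.  Two analysis routes are implemented:

Subtraction pipeline
    (1) remove decay correction; (2) fit a triexponential to the post-peak
    first-segment blood curve and extrapolate it over the second segment;
    (3) subtract the projection from the measured blood curve; (4) project
    each region's first-tracer tissue curve forward with its fitted 1TCM
    parameters driven by the projected input, and subtract; (5) reapply
    decay correction (referenced to the second injection) and fit the
    second tracer (2TCM-irreversible and Patlak).

Joint simultaneous fit
    Per region, a single weighted least-squares problem over the full
    schedule in the decay-uncorrected (measured) domain: the model is the
    decay-weighted sum of a 1TCM for the first tracer and a
    2TCM-irreversible model for the second, each driven by its own input
    component.  The separable strategy keeps only the two rate constants
    (k2 of the first tracer, theta of the second) nonlinear; the uptake
    amplitudes and a shared blood fraction are linear and solved in closed
    form at each candidate rate pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import graphical
from .fitting import (
    FitOptions,
    FitResult,
    FrameIntegrator,
    _solve_linear,
    fit_compartment,
    fit_separable,
    fit_triexponential,
)
from .kinetics import (
    FrameSchedule,
    InjectionEvent,
    OneTissueParams,
    PiecewiseLinearCurve,
    TimeActivityCurve,
    TwoTissueIrrevParams,
    average_preserving_interpolant,
    compute_suv,
    decay_correct,
    evaluate_onetcm,
    exp_conv,
    frame_average,
    frame_average_from_samples,
)

__all__ = [
    "DualTracerStudy",
    "StudySegments",
    "InputCorrection",
    "CorrectionResult",
    "AnalysisConfig",
    "decay_correct_study",
    "segment_study",
    "correct_input_function",
    "subtract_tissue_residual",
    "residual_fraction",
    "fit_second_tracer",
    "joint_dual_fit",
    "run_dual_tracer_analysis",
]


@dataclass(frozen=True)
class DualTracerStudy:
    """Two staggered injections plus blood and tissue curves on one schedule."""

    injections: tuple[InjectionEvent, InjectionEvent]
    input_curve: TimeActivityCurve
    tissue_curves: dict
    body_weight: float

    def __post_init__(self):
        if len(self.injections) != 2:
            raise ValueError("exactly two injections required")
        t1, t2 = (inj.injection_time for inj in self.injections)
        if not t2 > t1:
            raise ValueError("second injection must be strictly after the first")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        sched = self.input_curve.schedule
        for name, tac in self.tissue_curves.items():
            if tac.schedule.n_frames != sched.n_frames or not np.allclose(
                tac.schedule.start, sched.start
            ):
                raise ValueError(f"tissue curve {name!r} does not share the study schedule")
        if not (sched.start[0] <= t2 < sched.end[-1]):
            raise ValueError("schedule does not span both injections")

    @property
    def t_second(self) -> float:
        return float(self.injections[1].injection_time)


def decay_correct_study(study: DualTracerStudy) -> DualTracerStudy:
    """Decay-correct every curve to the first injection time (no-op if done)."""
    inj1 = study.injections[0]

    def corr(tac: TimeActivityCurve) -> TimeActivityCurve:
        if tac.decay_corrected:
            return tac
        return decay_correct(tac, inj1.half_life,
                             reference_time=inj1.injection_time, direction="apply")

    return DualTracerStudy(
        injections=study.injections,
        input_curve=corr(study.input_curve),
        tissue_curves={k: corr(v) for k, v in study.tissue_curves.items()},
        body_weight=study.body_weight,
    )


@dataclass(frozen=True)
class StudySegments:
    """Curves split at the second injection time (mid-time convention)."""

    t_split: float
    first_input: TimeActivityCurve
    second_input: TimeActivityCurve
    first_tissues: dict
    second_tissues: dict
    n_dropped: int


def _split_masks(schedule: FrameSchedule, t2: float):
    mid = schedule.mid
    straddle = (schedule.start < t2 - 1e-9) & (schedule.end > t2 + 1e-9)
    first = (mid < t2) & ~straddle
    second = (mid >= t2) & ~straddle
    return first, second, int(straddle.sum())


def segment_study(study: DualTracerStudy) -> StudySegments:
    """Split every curve at the second injection.

    Frames are assigned by mid-time; a frame whose boundary coincides with
    the injection time belongs to the second segment (half-open convention).
    Frames straddling the injection are dropped with a warning.
    """
    t2 = study.t_second
    sched = study.input_curve.schedule
    first, second, n_drop = _split_masks(sched, t2)
    if n_drop:
        warnings.warn(f"dropping {n_drop} frame(s) straddling the second injection")
    if not first.any() or not second.any():
        raise ValueError("segmentation produced an empty segment")
    return StudySegments(
        t_split=t2,
        first_input=study.input_curve.subset(first),
        second_input=study.input_curve.subset(second),
        first_tissues={k: v.subset(first) for k, v in study.tissue_curves.items()},
        second_tissues={k: v.subset(second) for k, v in study.tissue_curves.items()},
        n_dropped=n_drop,
    )


class _HybridInput:
    """First-tracer input over the whole study: measured before the switch
    time, triexponential projection after it."""

    def __init__(self, measured: PiecewiseLinearCurve, projection, t_switch: float):
        self.measured = measured
        self.projection = projection
        self.t_switch = t_switch

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where(t < self.t_switch, self.measured(t), self.projection(t))


@dataclass(frozen=True)
class InputCorrection:
    """Blood-curve correction products (all on the study clock)."""

    corrected_input: TimeActivityCurve        # decay-corrected, ref = 2nd injection
    corrected_input_unc: TimeActivityCurve    # before reapplying decay correction
    corrected_input_raw: np.ndarray           # before clipping
    projected_input: TimeActivityCurve        # decay-uncorrected projection, 2nd segment
    measured_second_unc: TimeActivityCurve
    first_input_unc: TimeActivityCurve
    triexp_fit: FitResult
    projection_model: _HybridInput
    n_clipped: int


def correct_input_function(study: DualTracerStudy,
                           triexp_fit_start: float = 5.0) -> InputCorrection:
    """Remove the first tracer's contribution from the blood input function.

    The input curve must arrive decay-corrected.  Correction is carried out
    in the decay-uncorrected (measured) domain: the post-peak first-segment
    blood curve is fit by a triexponential, extrapolated over the second
    segment, and subtracted frame-wise; negative results are clipped to zero
    and counted.  Decay correction is then reapplied with the second
    injection as reference.
    """
    if not study.input_curve.decay_corrected:
        raise ValueError("input curve must be decay-corrected on entry")
    inj1, inj2 = study.injections
    t2 = study.t_second
    unc = decay_correct(study.input_curve, inj1.half_life, direction="remove")
    first, second, _ = _split_masks(unc.schedule, t2)
    first_unc = unc.subset(first)
    second_unc = unc.subset(second)
    tri = fit_triexponential(first_unc, fit_start=triexp_fit_start)

    proj = frame_average(tri.params, second_unc.schedule)
    proj = proj.with_values(proj.values, region_label="blood_projected")
    raw = second_unc.values - proj.values
    n_clip = int(np.sum(raw < 0))
    corrected_unc = second_unc.with_values(np.clip(raw, 0.0, None),
                                           region_label="blood_corrected")
    corrected = decay_correct(corrected_unc, inj2.half_life,
                              reference_time=t2, direction="apply")
    hybrid = _HybridInput(average_preserving_interpolant(first_unc), tri.params, t2)
    return InputCorrection(
        corrected_input=corrected,
        corrected_input_unc=corrected_unc,
        corrected_input_raw=raw,
        projected_input=proj,
        measured_second_unc=second_unc,
        first_input_unc=first_unc,
        triexp_fit=tri,
        projection_model=hybrid,
        n_clipped=n_clip,
    )


@dataclass(frozen=True)
class CorrectionResult:
    """Tissue-curve correction products for the second segment."""

    corrected_tissues: dict            # decay-corrected, ref = 2nd injection
    corrected_tissues_unc: dict        # after subtraction, before decay reapplication
    corrected_tissues_raw: dict        # before clipping (plain arrays)
    projected_first_tracer: dict       # decay-uncorrected projected residual
    first_tracer_fits: dict
    n_clipped: dict
    input_correction: InputCorrection


def subtract_tissue_residual(study: DualTracerStudy,
                             first_tracer_fits: dict,
                             input_correction: InputCorrection) -> CorrectionResult:
    """Project and subtract the first tracer's tissue signal per region.

    ``first_tracer_fits`` are 1TCM fits obtained on the decay-uncorrected
    first-segment data; the fitted parameters, driven by the measured (then
    projected) first-tracer input, are evaluated forward over the second
    segment and subtracted from the measured curves.  Regions without a fit
    are skipped with a warning.
    """
    inj1, inj2 = study.injections
    t2 = study.t_second
    hybrid = input_correction.projection_model
    corrected, corrected_unc, raw_all, projected, n_clipped = {}, {}, {}, {}, {}
    for name, tac in study.tissue_curves.items():
        if name not in first_tracer_fits:
            warnings.warn(f"no first-tracer fit for region {name!r}; skipped")
            continue
        if not tac.decay_corrected:
            raise ValueError("study tissue curves must be decay-corrected on entry")
        unc = decay_correct(tac, inj1.half_life, direction="remove")
        _, second, _ = _split_masks(unc.schedule, t2)
        second_unc = unc.subset(second)
        fit = first_tracer_fits[name]
        sched2 = second_unc.schedule
        ts = np.unique(np.concatenate([
            sched2.start, sched2.end, np.arange(0.0, sched2.end[-1], 0.25),
            [0.0, sched2.end[-1]],
        ]))
        vals = evaluate_onetcm(fit.params, hybrid, ts)
        proj_vals = frame_average_from_samples(ts, vals, sched2)
        projected[name] = TimeActivityCurve(sched2, proj_vals,
                                            region_label=f"{name}_projected")
        raw = second_unc.values - proj_vals
        raw_all[name] = raw
        n_clipped[name] = int(np.sum(raw < 0))
        cu = second_unc.with_values(np.clip(raw, 0.0, None))
        corrected_unc[name] = cu
        corrected[name] = decay_correct(cu, inj2.half_life,
                                        reference_time=t2, direction="apply")
    return CorrectionResult(
        corrected_tissues=corrected,
        corrected_tissues_unc=corrected_unc,
        corrected_tissues_raw=raw_all,
        projected_first_tracer=projected,
        first_tracer_fits=first_tracer_fits,
        n_clipped=n_clipped,
        input_correction=input_correction,
    )


def residual_fraction(measured: float, corrected: float) -> float:
    """Percent of the measured value removed by correction: 100 (m - c) / m.

    The same uncorrected-denominator convention is used for parameter
    comparisons via ``100 * (corrected - uncorrected) / uncorrected``.
    """
    if measured <= 0:
        raise ValueError("measured value must be positive")
    return 100.0 * (measured - corrected) / measured


def fit_second_tracer(corrected_tissue: TimeActivityCurve,
                      corrected_input: TimeActivityCurve,
                      t2: float,
                      options: FitOptions | None = None,
                      method: str = "separable",
                      t_star_patlak: float = graphical.DEFAULT_TSTAR_PATLAK):
    """2TCM-irreversible and Patlak estimates with time re-zeroed to the
    second injection.  Returns ``(FitResult, GraphicalResult)``."""
    tissue = corrected_tissue.rezeroed(t2)
    blood = corrected_input.rezeroed(t2)
    fitter = fit_separable if method == "separable" else fit_compartment
    fit = fitter("2tcm-irrev", tissue, blood, options)
    pat = graphical.patlak_ki(tissue, blood, t_star=t_star_patlak)
    return fit, pat


# ---------------------------------------------------------------------------
# Joint simultaneous fit
# ---------------------------------------------------------------------------


def joint_dual_fit(study: DualTracerStudy,
                   options: FitOptions | None = None,
                   input_correction: InputCorrection | None = None,
                   regions: tuple | None = None,
                   n_coarse: int = 16) -> tuple[FitResult, FitResult]:
    """Fit both tracers simultaneously over the full schedule, per region.

    Works in the measured (decay-uncorrected) domain.  The input components
    come from the blood-curve correction step: the first tracer's input is
    the measured blood before the second injection and its triexponential
    projection after; the second tracer's input is the residual-corrected
    blood, zero before its injection.  Each component is decay-corrected to
    its own injection to drive the compartment kinetics and the model tissue
    curves are decay-weighted back to the measured domain, so the estimated
    micro-parameters keep their usual (decay-free) meaning.

    Returns two :class:`FitResult` objects (first tracer, second tracer);
    for multi-region studies the per-region parameter sets are carried in
    ``extras['per_region']`` and ``params`` holds the first region's set.
    """
    options = options or FitOptions()
    inj1, inj2 = study.injections
    t2 = study.t_second
    lam1, lam2 = inj1.decay_constant, inj2.decay_constant
    if input_correction is None:
        input_correction = correct_input_function(study)
    sched = study.input_curve.schedule
    _, second_mask, _ = _split_masks(sched, t2)
    if second_mask.sum() < 3:
        raise ValueError("second segment too short for a joint fit")
    regions = regions or tuple(study.tissue_curves)

    blood_unc = decay_correct(study.input_curve, inj1.half_life, direction="remove")
    hybrid_unc = input_correction.projection_model
    cu = input_correction.corrected_input_unc
    pl2 = average_preserving_interpolant(cu)

    tmax = float(sched.end[-1])
    grid = np.unique(np.concatenate([
        sched.start, sched.end, [0.0, tmax], np.arange(0.0, tmax, 0.25),
        hybrid_unc.measured.t, pl2.t,
    ]))
    grid = grid[(grid >= 0) & (grid <= tmax)]
    integ = FrameIntegrator(grid, sched)
    g1 = hybrid_unc(grid) * np.exp(lam1 * grid)            # corrected-domain Cp1
    g2 = pl2(grid) * np.exp(lam2 * np.clip(grid - t2, 0.0, None))
    d1 = np.exp(-lam1 * grid)
    d2 = np.exp(-lam2 * np.clip(grid - t2, 0.0, None))
    cum2 = integ(d2 * exp_conv(grid, g2, 0.0))
    Bb = blood_unc.values
    w = options.weights(sched)
    sw = np.sqrt(w)
    vb_ub = options.bounds["vB"][1]

    def basis1(k2):
        return integ(d1 * exp_conv(grid, g1, k2))

    def basis3(theta):
        return integ(d2 * exp_conv(grid, g2, theta))

    lo = max(options.bounds["k2"][0], 1e-3)
    k2_grid = np.geomspace(lo, options.bounds["k2"][1], n_coarse)
    th_grid = np.geomspace(lo, options.bounds["k2"][1] + options.bounds["k3"][1],
                           n_coarse)
    B1_cols = [basis1(k) for k in k2_grid]
    B3_cols = [basis3(t) for t in th_grid]

    first_params, second_params, objectives = {}, {}, {}
    total_eval = 0
    all_ok = True
    for name in regions:
        y = decay_correct(study.tissue_curves[name], inj1.half_life,
                          direction="remove").values

        def solve(B1, B3):
            A = np.column_stack([B1, cum2, B3, Bb])
            return _solve_linear(A, y, sw, vb_ub)

        best = None
        for i, k2c in enumerate(k2_grid):
            for j, thc in enumerate(th_grid):
                c, obj = solve(B1_cols[i], B3_cols[j])
                total_eval += 1
                if best is None or obj < best[0]:
                    best = (obj, k2c, thc)

        def neg_obj(z):
            _, obj = solve(basis1(math.exp(z[0])), basis3(math.exp(z[1])))
            return obj

        res = minimize(neg_obj, x0=np.log([best[1], best[2]]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 400})
        total_eval += res.nfev
        k2_1, theta_2 = float(math.exp(res.x[0])), float(math.exp(res.x[1]))
        c, obj = solve(basis1(k2_1), basis3(theta_2))
        c1, a1, a2, vB = (float(v) for v in c)
        one_minus = max(1.0 - vB, 1e-12)
        first_params[name] = OneTissueParams(
            K1=c1 / one_minus, k2=max(k2_1, 1e-8), vB=min(vB, 1 - 1e-12))
        s = a1 + a2
        if s <= 1e-12:
            second_params[name] = TwoTissueIrrevParams(
                K1=0.0, k2=max(theta_2, 1e-8), k3=0.0, vB=min(vB, 1 - 1e-12))
        else:
            second_params[name] = TwoTissueIrrevParams(
                K1=s / one_minus, k2=max(theta_2 * a2 / s, 1e-8),
                k3=theta_2 * a1 / s, vB=min(vB, 1 - 1e-12))
        objectives[name] = obj
        all_ok = all_ok and bool(res.success)

    total_obj = float(sum(objectives.values()))
    first = next(iter(regions))
    fit1 = FitResult(params=first_params[first], objective=total_obj,
                     param_se={}, converged=all_ok, n_iter=total_eval,
                     method_tag="joint-separable",
                     extras={"per_region": first_params,
                             "objectives": objectives})
    fit2 = FitResult(params=second_params[first], objective=total_obj,
                     param_se={}, converged=all_ok, n_iter=total_eval,
                     method_tag="joint-separable",
                     extras={"per_region": second_params,
                             "objectives": objectives})
    return fit1, fit2


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Configuration for the end-to-end dual-tracer analysis."""

    options: FitOptions = field(default_factory=FitOptions)
    method: str = "separable"           # "separable" or "lm"
    t_star_logan: float = graphical.DEFAULT_TSTAR_LOGAN
    t_star_patlak: float = graphical.DEFAULT_TSTAR_PATLAK
    triexp_fit_start: float = 5.0
    do_correction: bool = True
    do_joint: bool = True
    regions: tuple | None = None


def run_dual_tracer_analysis(study: DualTracerStudy,
                             config: AnalysisConfig | None = None) -> dict:
    """Run the full analysis and return a machine-readable report.

    Stages: segmentation; first-tracer 1TCM + Logan fits (decay-corrected,
    referenced to the first injection); blood and tissue residual
    correction; second-tracer 2TCM-irreversible + Patlak fits with and
    without correction; joint simultaneous fit; final-frame residual
    fractions and SUVs.  Curves that arrive decay-uncorrected are first
    corrected to the first injection.  Per-region stage failures are
    recorded in the report and the pipeline continues where possible.
    """
    config = config or AnalysisConfig()
    options = config.options
    study = decay_correct_study(study)
    inj1, inj2 = study.injections
    t2 = study.t_second
    regions = config.regions or tuple(study.tissue_curves)
    fitter = fit_separable if config.method == "separable" else fit_compartment

    segs = segment_study(study)
    report: dict = {
        "study": {
            "tracers": [inj1.tracer_name, inj2.tracer_name],
            "injected_activity_MBq": [inj1.injected_activity, inj2.injected_activity],
            "injection_time_min": [inj1.injection_time, inj2.injection_time],
            "body_weight_kg": study.body_weight,
            "n_frames": study.input_curve.schedule.n_frames,
        },
        "regions": {},
        "errors": {},
    }

    # --- first-tracer fits on decay-corrected first-segment data ------------
    first_fits_corr = {}
    for name in regions:
        try:
            fit = fitter("1tcm", segs.first_tissues[name], segs.first_input, options)
            logan = graphical.logan_vt(segs.first_tissues[name], segs.first_input,
                                       t_star=config.t_star_logan)
            first_fits_corr[name] = (fit, logan)
        except Exception as exc:  # per-region failures are non-fatal
            report["errors"][f"first_tracer/{name}"] = str(exc)

    # --- correction in the measured domain ----------------------------------
    corr_result = None
    joint = None
    if config.do_correction or config.do_joint:
        unc_fits = {}
        input_unc = decay_correct(study.input_curve, inj1.half_life, direction="remove")
        first_mask, second_mask, _ = _split_masks(input_unc.schedule, t2)
        first_input_unc = input_unc.subset(first_mask)
        for name in regions:
            try:
                tac_unc = decay_correct(study.tissue_curves[name], inj1.half_life,
                                        direction="remove").subset(first_mask)
                unc_fits[name] = fitter("1tcm", tac_unc, first_input_unc, options)
            except Exception as exc:
                report["errors"][f"first_tracer_unc/{name}"] = str(exc)
        input_corr = correct_input_function(study, config.triexp_fit_start)
        corr_result = subtract_tissue_residual(study, unc_fits, input_corr)
        report["correction"] = {
            "n_clipped_input": input_corr.n_clipped,
            "n_clipped_tissue": corr_result.n_clipped,
            "triexp_objective": input_corr.triexp_fit.objective,
        }

    # --- measured (uncorrected) second-segment curves, re-referenced to t2 --
    _, second_mask, _ = _split_masks(study.input_curve.schedule, t2)

    def rereference(tac: TimeActivityCurve) -> TimeActivityCurve:
        unc = decay_correct(tac, inj1.half_life, direction="remove")
        return decay_correct(unc.subset(second_mask), inj2.half_life,
                             reference_time=t2, direction="apply")

    measured_second = {name: rereference(study.tissue_curves[name]) for name in regions}
    measured_input_second = rereference(study.input_curve)

    if config.do_joint:
        try:
            joint = joint_dual_fit(study, options,
                                   input_correction=corr_result.input_correction,
                                   regions=regions)
        except Exception as exc:
            report["errors"]["joint"] = str(exc)

    inj2_local = InjectionEvent(inj2.tracer_name, inj2.injected_activity,
                                t2, inj2.half_life)
    for name in regions:
        entry: dict = {}
        if name in first_fits_corr:
            fit, logan = first_fits_corr[name]
            entry["first_tracer"] = {
                "VT_compartment": fit.params.vt,
                "VT_logan": logan.estimate,
                "logan_r_squared": logan.r_squared,
                "fit": fit.to_dict(),
            }
        try:
            ufit, upat = fit_second_tracer(
                measured_second[name], measured_input_second, t2,
                options, config.method, config.t_star_patlak)
            st = entry.setdefault("second_tracer", {})
            st["Ki_uncorrected"] = ufit.params.ki
            st["Ki_patlak_uncorrected"] = upat.estimate
        except Exception as exc:
            report["errors"][f"second_uncorrected/{name}"] = str(exc)
        if corr_result is not None and name in corr_result.corrected_tissues:
            try:
                cfit, cpat = fit_second_tracer(
                    corr_result.corrected_tissues[name],
                    corr_result.input_correction.corrected_input, t2,
                    options, config.method, config.t_star_patlak)
                st = entry.setdefault("second_tracer", {})
                st["Ki_corrected"] = cfit.params.ki
                st["Ki_patlak_corrected"] = cpat.estimate
                if st.get("Ki_uncorrected", 0) > 0:
                    st["Ki_pct_change_on_correction"] = 100.0 * (
                        st["Ki_corrected"] - st["Ki_uncorrected"]
                    ) / st["Ki_uncorrected"]
                meas_final = float(measured_second[name].values[-1])
                corr_final = float(corr_result.corrected_tissues[name].values[-1])
                if meas_final > 0:
                    entry["residual"] = {
                        "final_frame_pct": residual_fraction(meas_final, corr_final),
                        "suv_measured_final": float(compute_suv(
                            measured_second[name], inj2_local, study.body_weight)[-1]),
                        "suv_corrected_final": float(compute_suv(
                            corr_result.corrected_tissues[name], inj2_local,
                            study.body_weight)[-1]),
                    }
            except Exception as exc:
                report["errors"][f"second_corrected/{name}"] = str(exc)
        if joint is not None:
            f1, f2 = joint
            p1 = f1.extras["per_region"].get(name)
            p2 = f2.extras["per_region"].get(name)
            if p1 is not None:
                entry.setdefault("joint", {})["VT_first"] = p1.vt
            if p2 is not None:
                entry.setdefault("joint", {})["Ki_second"] = p2.ki
        report["regions"][name] = entry
    return report
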
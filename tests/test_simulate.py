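"""Synthetic-data generator: input shapes, noise model, thinning, additivity."""

from dataclasses import replace

import numpy as np
import pytest

from dualtracer.fitting import fit_triexponential
from dualtracer.kinetics import (
    InjectionEvent,
    OneTissueParams,
    TimeActivityCurve,
    compute_suv,
    decay_correct,
    frame_average,
)
from dualtracer.simulate import (
    InputShape,
    add_noise,
    default_dual_truth,
    default_single_truth,
    generate_input_function,
    simulate_dual_tracer_study,
    simulate_study,
    simulate_tissue_tac,
    single_tracer_schedule,
    thin_dose,
)


class TestInputFunction:
    def test_zero_before_injection_and_linearity(self):
        inj = InjectionEvent("FGln", 41.0, 10.0)
        model = generate_input_function(inj)
        assert np.all(model(np.array([0.0, 5.0, 9.99])) == 0.0)
        double = generate_input_function(InjectionEvent("FGln", 82.0, 10.0))
        t = np.linspace(10.0, 60.0, 50)
        assert np.allclose(double(t), 2.0 * model(t), rtol=1e-12)

    def test_peak_within_first_minute(self):
        model = generate_input_function(InjectionEvent("FGln", 41.0, 0.0))
        t = np.linspace(0, 5, 2001)
        assert 0.3 < t[np.argmax(model(t))] < 1.2

    def test_tail_consistent_with_triexp_correction_model(self):
        """The generated tail must be representable by the projection model
        the correction pipeline fits (relative residual < 1%)."""
        inj = InjectionEvent("FGln", 41.0, 0.0)
        model = generate_input_function(inj)
        sched = single_tracer_schedule(70.0)
        blood = frame_average(model.measured, sched)
        fit = fit_triexponential(blood, fit_start=5.0)
        mask = sched.mid >= 5.0
        pred = frame_average(fit.params, sched.subset(mask)).values
        resid = np.abs(pred - blood.values[mask]) / blood.values[mask]
        assert np.max(resid) < 0.01

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            InputShape(rates=(1.0, -0.1, 0.01))


class TestTissueSimulation:
    def test_no_uptake_no_blood_is_zero(self):
        inj = InjectionEvent("FGln", 41.0, 0.0)
        model = generate_input_function(inj)
        tac = simulate_tissue_tac(OneTissueParams(K1=0.0, k2=0.1, vB=0.0),
                                  model, single_tracer_schedule(70.0))
        assert np.allclose(tac.values, 0.0)

    def test_tumor_suv_in_expected_range(self):
        """Paper-regime doses/weight put the tumor on the SUV scale of a
        clinical scan (roughly 1-7)."""
        truth = default_dual_truth(regions=("tumor",), noise_scale=0.0)
        study, sim = simulate_dual_tracer_study(truth)
        inj2 = truth.injections[1]
        mask = sim.schedule.mid >= inj2.injection_time
        second = decay_correct(study.tissue_curves["tumor"].subset(mask),
                               inj2.half_life, inj2.injection_time)
        suv = compute_suv(second, inj2, truth.body_weight)
        assert 1.0 < suv.max() < 7.0


class TestNoise:
    def test_zero_scale_is_identity(self):
        truth = default_single_truth(noise_scale=0.0)
        sim = simulate_study(truth)
        tac = sim.tissues["tumor"]
        assert add_noise(tac, 0.0, 123) is tac

    def test_variance_calibration(self):
        """Empirical per-frame variance over 1000 replicates matches
        noise_scale * C / dt within 10% (frames where clipping is rare)."""
        inj = InjectionEvent("FGln", 41.0, 0.0)
        model = generate_input_function(inj)
        sched = single_tracer_schedule(70.0)
        tac = simulate_tissue_tac(OneTissueParams(0.12, 0.2, 0.05), model, sched)
        scale = 0.01
        rng = np.random.default_rng(0)
        draws = np.array([add_noise(tac, scale, rng).values for _ in range(1000)])
        var_theo = scale * tac.values / sched.duration
        sel = tac.values / np.sqrt(var_theo) > 5
        assert sel.sum() > 10
        ratio = draws.var(axis=0)[sel] / var_theo[sel]
        assert np.max(np.abs(ratio - 1.0)) < 0.10

    def test_noise_requires_uncorrected_curve(self):
        truth = default_single_truth()
        sim = simulate_study(truth)
        corrected = decay_correct(sim.tissues["tumor"], 109.77, 0.0)
        with pytest.raises(ValueError):
            add_noise(corrected, 0.01, 1)

    def test_determinism_and_seed_sensitivity(self):
        truth = default_dual_truth(regions=("tumor",), seed=5)
        a = simulate_study(truth)
        b = simulate_study(truth)
        assert np.array_equal(a.tissues["tumor"].values, b.tissues["tumor"].values)
        c = simulate_study(replace(truth, seed=6))
        assert not np.array_equal(a.tissues["tumor"].values,
                                  c.tissues["tumor"].values)
        # noiseless components identical across seeds
        assert np.array_equal(a.components["tumor"][0].values,
                              c.components["tumor"][0].values)


class TestThinning:
    def test_identity_and_range(self):
        truth = default_single_truth()
        sim = simulate_study(truth)
        assert thin_dose(sim, 1.0, seed=0) is sim
        with pytest.raises(ValueError):
            thin_dose(sim, 0.0, seed=0)
        with pytest.raises(ValueError):
            thin_dose(sim, 1.5, seed=0)

    def test_activity_metadata_scaled(self):
        truth = default_dual_truth(regions=("tumor",))
        sim = simulate_study(truth)
        half = thin_dose(sim, 0.5, seed=1)
        assert half.injections[0].injected_activity == pytest.approx(20.5)
        assert half.injections[1].injected_activity == pytest.approx(197.0)

    def test_renormalised_mean_unbiased(self):
        inj = InjectionEvent("FGln", 41.0, 0.0)
        model = generate_input_function(inj)
        sched = single_tracer_schedule(70.0)
        tac = simulate_tissue_tac(OneTissueParams(0.12, 0.2, 0.05), model, sched)
        draws = np.array([
            thin_dose(tac, 0.5, seed=r, noise_scale=0.01).values
            for r in range(1000)])
        var_theo = 0.01 * tac.values / sched.duration
        sel = tac.values / np.sqrt(var_theo) > 5
        rel = np.abs(draws.mean(axis=0)[sel] / tac.values[sel] - 1.0)
        assert np.max(rel) < 0.02

    def test_half_dose_raises_relative_noise_sqrt2(self):
        """Thinning a full-noise curve to half dose scales the count variance
        by 1/fraction, i.e. relative noise grows by about sqrt(2)."""
        inj = InjectionEvent("FGln", 41.0, 0.0)
        model = generate_input_function(inj)
        sched = single_tracer_schedule(70.0)
        clean = simulate_tissue_tac(OneTissueParams(0.12, 0.2, 0.05), model, sched)
        scale = 0.01
        full = np.array([add_noise(clean, scale, np.random.default_rng(r)).values
                         for r in range(800)])
        half = np.array([
            thin_dose(add_noise(clean, scale, np.random.default_rng(r)),
                      0.5, seed=10000 + r, noise_scale=scale).values
            for r in range(800)])
        var_theo = scale * clean.values / sched.duration
        sel = clean.values / np.sqrt(var_theo) > 5
        ratio = np.median(half.std(axis=0)[sel] / full.std(axis=0)[sel])
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.10)


class TestDualStudyAssembly:
    def test_component_additivity(self):
        truth = default_dual_truth(noise_scale=0.0)
        study, sim = simulate_dual_tracer_study(truth)
        for name, tac in study.tissue_curves.items():
            total = sum(c.values for c in sim.components[name])
            assert np.allclose(tac.values, total, rtol=1e-12, atol=1e-14)
        total_blood = sum(c.values for c in sim.components["blood"])
        assert np.allclose(study.input_curve.values, total_blood, rtol=1e-12)

    def test_schedule_must_have_boundary_at_second_injection(self):
        truth = default_dual_truth(regions=("tumor",))
        bad = replace(truth, schedule=single_tracer_schedule(70.0))
        with pytest.raises(ValueError):
            simulate_study(bad)

    def test_null_second_tracer_reduces_to_single(self):
        truth = default_dual_truth(regions=("tumor",), noise_scale=0.0)
        null2 = replace(truth, shapes=(truth.shapes[0],
                                       InputShape(amplitudes=(0.0, 0.0, 0.0))))
        study, sim = simulate_dual_tracer_study(null2)
        assert np.allclose(sim.components["blood"][1].values, 0.0)
        assert np.allclose(study.input_curve.values,
                           sim.components["blood"][0].values, rtol=1e-12)
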
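"""Domain types, forward models, decay correction, frame averaging, SUV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualtracer.kinetics import (
    FrameSchedule,
    InjectionEvent,
    OneTissueParams,
    TimeActivityCurve,
    TriexpParams,
    TwoTissueIrrevParams,
    average_preserving_interpolant,
    compute_suv,
    decay_correct,
    evaluate_onetcm,
    evaluate_twotcm_irrev,
    frame_average,
    macro_params,
    net_influx_rate,
    volume_of_distribution,
)


def constant_input(t):
    return np.where(np.asarray(t, dtype=float) >= 0, 1.0, 0.0)


TRIEXP_INPUT = TriexpParams((20.0, 5.0, 1.0), (0.5, 0.08, 0.01))


class TestSchedule:
    def test_from_blocks_and_properties(self):
        s = FrameSchedule.from_blocks([(2, 0.5), (1, 1.0)])
        assert np.allclose(s.start, [0.0, 0.5, 1.0])
        assert np.allclose(s.mid, [0.25, 0.75, 1.5])
        assert s.span == (0.0, 2.0)

    @pytest.mark.parametrize("start,dur", [
        ([0.0, 0.5], [1.0, 1.0]),      # overlap
        ([1.0, 0.5], [0.2, 0.2]),      # not increasing
        ([0.0], [0.0]),                # zero duration
    ])
    def test_invalid_schedules_rejected(self, start, dur):
        with pytest.raises(ValueError):
            FrameSchedule(start, dur)

    def test_tac_validation(self):
        s = FrameSchedule.from_blocks([(3, 1.0)])
        with pytest.raises(ValueError):
            TimeActivityCurve(s, [1.0, 2.0])  # wrong length
        with pytest.raises(ValueError):
            TimeActivityCurve(s, [1.0, 2.0, 3.0], decay_corrected=True)  # no ref


class TestForwardModels:
    def test_no_uptake_reduces_to_blood_fraction(self):
        p = OneTissueParams(K1=0.0, k2=0.1, vB=0.05)
        t = np.array([1.0, 5.0, 20.0])
        out = evaluate_onetcm(p, TRIEXP_INPUT, t)
        assert np.allclose(out, 0.05 * TRIEXP_INPUT(t), rtol=1e-10)

    def test_onetcm_constant_input_closed_form(self):
        p = OneTissueParams(K1=0.1, k2=0.2, vB=0.0)
        out = evaluate_onetcm(p, constant_input, [5.0])
        assert out[0] == pytest.approx(0.5 * (1 - np.exp(-1.0)), rel=1e-4)

    def test_twotcm_constant_input_closed_form(self):
        p = TwoTissueIrrevParams(K1=0.1, k2=0.1, k3=0.02, vB=0.0)
        out = evaluate_twotcm_irrev(p, constant_input, [10.0])
        expected = 0.1 * (0.02 / 0.12 * 10 + 0.1 / 0.12**2 * (1 - np.exp(-1.2)))
        assert out[0] == pytest.approx(expected, rel=1e-4)

    def test_twotcm_late_slope_is_ki(self):
        p = TwoTissueIrrevParams(K1=0.1, k2=0.1, k3=0.02, vB=0.0)
        t = np.array([60.0, 61.0, 80.0, 81.0])
        out = evaluate_twotcm_irrev(p, constant_input, t)
        slope = (out[3] - out[2])
        assert slope == pytest.approx(p.ki, rel=1e-3)

    def test_model_nesting_k3_zero(self):
        t = np.linspace(0.5, 40, 20)
        p2 = TwoTissueIrrevParams(K1=0.12, k2=0.2, k3=0.0, vB=0.03)
        p1 = OneTissueParams(K1=0.12, k2=0.2, vB=0.03)
        a = evaluate_twotcm_irrev(p2, TRIEXP_INPUT, t)
        b = evaluate_onetcm(p1, TRIEXP_INPUT, t)
        assert np.allclose(a, b, rtol=1e-10, atol=1e-14)

    def test_negative_times_rejected(self):
        p = OneTissueParams(K1=0.1, k2=0.1)
        with pytest.raises(ValueError):
            evaluate_onetcm(p, constant_input, [-1.0, 2.0])

    @pytest.mark.parametrize("kwargs", [
        {"K1": 0.1, "k2": 0.0},
        {"K1": -0.1, "k2": 0.1},
        {"K1": 0.1, "k2": 0.1, "vB": 1.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OneTissueParams(**kwargs)

    def test_convolution_matches_bruteforce(self):
        """Both evaluators vs dense-grid (0.001 min) numerical convolution."""
        rng = np.random.default_rng(11)
        times = np.linspace(1.0, 30.0, 8)
        fine = np.arange(0.0, 30.0005, 0.001)
        cp = TRIEXP_INPUT(fine)
        for _ in range(20):
            K1 = rng.uniform(0.01, 0.5)
            k2 = rng.uniform(0.05, 1.0)
            k3 = rng.uniform(0.0, 0.2)
            ref1, ref2 = [], []
            for t in times:
                m = fine <= t
                ker = np.exp(-k2 * (t - fine[m]))
                ref1.append(K1 * np.trapezoid(ker * cp[m], fine[m]))
                th = k2 + k3
                conv = np.trapezoid(np.exp(-th * (t - fine[m])) * cp[m], fine[m])
                cum = np.trapezoid(cp[m], fine[m])
                ref2.append(K1 * (k3 / th * cum + k2 / th * conv))
            got1 = evaluate_onetcm(OneTissueParams(K1, k2), TRIEXP_INPUT, times)
            got2 = evaluate_twotcm_irrev(
                TwoTissueIrrevParams(K1, k2, k3), TRIEXP_INPUT, times)
            scale1, scale2 = np.max(ref1), np.max(ref2)
            assert np.max(np.abs(got1 - ref1)) / scale1 < 1e-3
            assert np.max(np.abs(got2 - ref2)) / scale2 < 1e-3

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(K1=st.floats(0.01, 0.5), k2=st.floats(0.05, 1.0),
           c=st.floats(0.1, 10.0))
    def test_linearity_in_input(self, K1, k2, c):
        """Scaling the input by c scales blood-free model output by c."""
        p = OneTissueParams(K1=K1, k2=k2, vB=0.0)
        t = np.array([2.0, 10.0, 25.0])
        base = evaluate_onetcm(p, lambda x: TRIEXP_INPUT(x), t)
        scaled = evaluate_onetcm(p, lambda x: c * TRIEXP_INPUT(x), t)
        assert np.allclose(scaled, c * base, rtol=1e-9)


class TestDecayCorrection:
    def make_curve(self):
        s = FrameSchedule.from_blocks([(5, 2.0)])
        return TimeActivityCurve(s, [1.0, 2.0, 3.0, 2.0, 1.0],
                                 decay_corrected=True, decay_reference_time=0.0)

    def test_round_trip_identity(self):
        c = self.make_curve()
        back = decay_correct(
            decay_correct(c, 109.77, direction="remove"),
            109.77, reference_time=0.0, direction="apply")
        assert np.allclose(back.values, c.values, rtol=1e-14)

    def test_half_life_definition(self):
        s = FrameSchedule([109.77 - 1.0], [2.0])  # mid-time exactly one T_half
        c = TimeActivityCurve(s, [1.0], decay_corrected=True,
                              decay_reference_time=0.0)
        removed = decay_correct(c, 109.77, direction="remove")
        assert removed.values[0] == pytest.approx(0.5, rel=1e-12)

    def test_rereference_constant_factor(self):
        c = self.make_curve()
        lam = np.log(2) / 109.77
        re = decay_correct(
            decay_correct(c, 109.77, direction="remove"),
            109.77, reference_time=29.0, direction="apply")
        assert np.allclose(re.values, c.values * np.exp(-lam * 29.0), rtol=1e-12)

    def test_double_application_rejected(self):
        c = self.make_curve()
        with pytest.raises(ValueError):
            decay_correct(c, 109.77, reference_time=0.0, direction="apply")
        u = decay_correct(c, 109.77, direction="remove")
        with pytest.raises(ValueError):
            decay_correct(u, 109.77, direction="remove")


class TestFrameAverage:
    def test_constant_and_linear(self):
        s = FrameSchedule.from_blocks([(1, 2.0), (1, 3.0)])
        const = frame_average(lambda t: np.full_like(np.asarray(t, float), 4.2), s)
        assert np.allclose(const.values, 4.2)
        lin = frame_average(lambda t: 3.0 * np.asarray(t, float), s)
        assert lin.values[0] == pytest.approx(3.0 * 1.0, rel=1e-12)  # midpoint

    def test_exponential_analytic(self):
        s = FrameSchedule([0.0], [4.0])
        out = frame_average(lambda t: np.exp(-0.2 * np.asarray(t, float)), s)
        assert out.values[0] == pytest.approx((1 - np.exp(-0.8)) / 0.8, rel=1e-5)

    def test_average_preserving_interpolant_round_trip(self):
        """Reconstruction frame averages reproduce the data they came from."""
        s = FrameSchedule.from_blocks([(6, 0.5), (4, 2.0)])
        rng = np.random.default_rng(3)
        tac = TimeActivityCurve(s, rng.uniform(1.0, 5.0, s.n_frames))
        pl = average_preserving_interpolant(tac)
        # integrate on a grid containing the knots: exact for piecewise-linear
        from dualtracer.kinetics import frame_average_from_samples
        grid = np.unique(np.concatenate([pl.t, s.start, s.end]))
        back = frame_average_from_samples(grid, pl(grid), s)
        assert np.allclose(back, tac.values, rtol=1e-8, atol=1e-10)


class TestMacroAndSuv:
    def test_macro_parameters(self):
        assert volume_of_distribution(OneTissueParams(0.12, 0.2)) == pytest.approx(0.6)
        p = TwoTissueIrrevParams(0.1, 0.1, 0.02)
        assert net_influx_rate(p) == pytest.approx(1 / 60, rel=1e-12)
        assert macro_params(TwoTissueIrrevParams(0.1, 0.1, 0.0)) == 0.0

    def test_suv_identity_and_protocol_value(self):
        s = FrameSchedule.from_blocks([(2, 2.0)])
        inj = InjectionEvent("FDG", 394.0, 0.0)
        # concentration equal to injected-per-weight -> SUV 1
        c0 = 394.0 / 93.5
        tac = TimeActivityCurve(s, [c0, 12.5], decay_corrected=True,
                                decay_reference_time=0.0)
        suv = compute_suv(tac, inj, 93.5)
        assert suv[0] == pytest.approx(1.0, rel=1e-12)
        assert suv[1] == pytest.approx(12.5 / (394000.0 / 93500.0), rel=1e-9)

    def test_suv_preconditions(self):
        s = FrameSchedule.from_blocks([(1, 2.0)])
        inj = InjectionEvent("FDG", 394.0, 0.0)
        raw = TimeActivityCurve(s, [1.0])
        with pytest.raises(ValueError):
            compute_suv(raw, inj, 93.5)  # not decay-corrected
        ok = TimeActivityCurve(s, [1.0], decay_corrected=True,
                               decay_reference_time=0.0)
        with pytest.raises(ValueError):
            compute_suv(ok, inj, -1.0)
        shifted = TimeActivityCurve(s, [1.0], decay_corrected=True,
                                    decay_reference_time=5.0)
        with pytest.raises(ValueError):
            compute_suv(shifted, inj, 93.5)  # wrong reference
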
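"""Synthetic ground-truth generator for single- and dual-tracer studies.

Raw patient data for this kind of protocol are rarely shared, so the
package carries its own generator that emulates the measurement chain of a
staggered two-injection study on a high-sensitivity scanner:

* an image-derived blood input function shaped as a bolus (smooth rise over
  ~0.5-1 min) followed by a triexponential washout, scaled linearly with the
  injected activity;
* tissue curves produced by the 1TCM / 2TCM-irreversible forward models;
* physical decay applied per injection, so all simulated frame data are
  decay-UNcorrected, as they come off a scanner before correction;
* both tracers summed on a shared frame schedule with a frame boundary at
  the second injection time;
* count-limited Gaussian noise whose variance scales with the
  decay-uncorrected frame value and inversely with frame duration, so lower
  doses and shorter frames are noisier;
* dose thinning that emulates list-mode subsampling at the curve level.

The default dual-tracer truth mirrors the protocol this package targets:
41 MBq of the first tracer at t = 0 with a 29-min segment, then 394 MBq of
the second tracer with a 60-min segment, a 93.5-kg subject, a tumor with
V_T ~ 0.6 mL/cm^3 (1TCM) and K_i ~ 0.015 mL/min/cm^3 (2TCM-irrev).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import (
    FrameSchedule,
    InjectionEvent,
    OneTissueParams,
    TimeActivityCurve,
    TwoTissueIrrevParams,
    evaluate_onetcm,
    evaluate_twotcm_irrev,
    frame_average_from_samples,
)

__all__ = [
    "DEFAULT_NOISE_SCALE",
    "InputShape",
    "BloodInputModel",
    "SyntheticTruth",
    "SimulatedStudy",
    "generate_input_function",
    "simulate_tissue_tac",
    "add_noise",
    "thin_dose",
    "simulate_study",
    "simulate_dual_tracer_study",
    "default_dual_truth",
    "default_single_truth",
    "dual_tracer_schedule",
    "single_tracer_schedule",
]

#: Count-noise scale (kBq^2 min / mL^2 per kBq/mL): variance of a frame is
#: noise_scale * value / duration.  Chosen so that a ~40-MBq tracer yields a
#: few-percent coefficient of variation on late 4-min frames, and quarter-dose
#: data become visibly unstable, matching the regime the protocol probes.
DEFAULT_NOISE_SCALE = 0.01


def dual_tracer_schedule(t2: float = 29.0, end: float = 89.0) -> FrameSchedule:
    """Default dual-tracer framing with a frame boundary exactly at ``t2``.

    First segment: 12x10 s, 6x30 s, 5x60 s, 4-min frames, closing 3-min
    frame to ``t2``; second segment restarts fine framing at ``t2`` and ends
    with 5-min frames.
    """
    first = [(12, 10 / 60), (6, 0.5), (5, 1.0), (4, 4.0), (1, 3.0)]
    sched1 = FrameSchedule.from_blocks(first)
    if abs(sched1.end[-1] - t2) > 1e-9:
        raise ValueError("first-segment blocks must end at t2")
    second = [(12, 10 / 60), (6, 0.5), (5, 1.0), (5, 4.0), (6, 5.0)]
    sched2 = FrameSchedule.from_blocks(second, t0=t2)
    if abs(sched2.end[-1] - end) > 1e-9:
        raise ValueError("second-segment blocks must end at the scan end")
    return FrameSchedule(
        np.concatenate([sched1.start, sched2.start]),
        np.concatenate([sched1.duration, sched2.duration]),
    )


def single_tracer_schedule(duration: float = 70.0) -> FrameSchedule:
    """Default single-tracer framing: fine early frames, then 4-min frames."""
    n4 = int(round((duration - 10.0) / 4.0))
    if 10.0 + 4.0 * n4 != duration:
        raise ValueError("duration must be 10 + multiple of 4 minutes")
    return FrameSchedule.from_blocks([(12, 10 / 60), (6, 0.5), (5, 1.0), (n4, 4.0)])


@dataclass(frozen=True)
class InputShape:
    """Shape of the image-derived blood curve, per MBq injected.

    ``amplitudes`` (kBq/mL per MBq) and ``rates`` (1/min) describe the
    triexponential washout; the bolus rise is a saturating exponential with
    time constant ``rise_time`` (min), putting the peak ~0.5-1 min after
    injection.  Beyond a few minutes the curve is exactly triexponential.
    """

    amplitudes: tuple[float, float, float] = (0.18, 0.05, 0.035)
    rates: tuple[float, float, float] = (3.0, 0.3, 0.012)
    rise_time: float = 0.3

    def __post_init__(self):
        if len(self.amplitudes) != 3 or len(self.rates) != 3:
            raise ValueError("three amplitudes and three rates required")
        if any(a < 0 for a in self.amplitudes) or any(r <= 0 for r in self.rates):
            raise ValueError("amplitudes must be >= 0 and rates > 0")
        if self.rise_time <= 0:
            raise ValueError("rise_time must be positive")


class BloodInputModel:
    """Continuous decay-corrected-to-injection blood curve for one tracer.

    Zero before the injection time; scales linearly with injected activity.
    """

    def __init__(self, injection: InjectionEvent, shape: InputShape):
        self.injection = injection
        self.shape = shape

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = t - self.injection.injection_time
        out = np.zeros_like(tau)
        live = tau >= 0
        tl = tau[live]
        tail = np.zeros_like(tl)
        for a, r in zip(self.shape.amplitudes, self.shape.rates):
            tail += a * np.exp(-r * tl)
        out[live] = (
            self.injection.injected_activity
            * (1.0 - np.exp(-tl / self.shape.rise_time))
            * tail
        )
        return out

    def measured(self, t) -> np.ndarray:
        """Decay-uncorrected (physically measured) concentration."""
        t = np.asarray(t, dtype=float)
        lam = self.injection.decay_constant
        return self(t) * np.exp(-lam * np.maximum(t - self.injection.injection_time, 0.0))


def generate_input_function(injection: InjectionEvent,
                            shape: InputShape | None = None) -> BloodInputModel:
    """Continuous blood input model for one injection."""
    return BloodInputModel(injection, shape or InputShape())


@dataclass(frozen=True)
class RegionTruth:
    """True kinetic parameters of one region, one entry per tracer.

    Entries are ``OneTissueParams`` or ``TwoTissueIrrevParams`` (or ``None``
    if the region does not take up that tracer).
    """

    name: str
    params: tuple

    def __post_init__(self):
        for p in self.params:
            if p is not None and not isinstance(p, (OneTissueParams, TwoTissueIrrevParams)):
                raise TypeError("params entries must be compartment parameter sets or None")


@dataclass(frozen=True)
class SyntheticTruth:
    """Complete ground truth for a simulated study; reproducible by seed."""

    injections: tuple[InjectionEvent, ...]
    schedule: FrameSchedule
    regions: tuple[RegionTruth, ...]
    shapes: tuple[InputShape, ...]
    body_weight: float = 93.5
    noise_scale: float = DEFAULT_NOISE_SCALE
    seed: int = 0

    def __post_init__(self):
        if len(self.injections) not in (1, 2):
            raise ValueError("one or two injections supported")
        if len(self.shapes) != len(self.injections):
            raise ValueError("one input shape per injection required")
        for r in self.regions:
            if len(r.params) != len(self.injections):
                raise ValueError("each region needs one parameter set per tracer")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def rng_for(self, label: str) -> np.random.Generator:
        sub = zlib.crc32(label.encode()) & 0x7FFFFFFF
        return np.random.default_rng([self.seed & 0x7FFFFFFF, sub])


def default_dual_truth(seed: int = 0,
                       noise_scale: float = DEFAULT_NOISE_SCALE,
                       first_activity: float = 41.0,
                       second_activity: float = 394.0,
                       t2: float = 29.0,
                       regions: tuple[str, ...] | None = None) -> SyntheticTruth:
    """Paper-regime dual-tracer truth: 41 MBq then 394 MBq offset by 29 min."""
    inj1 = InjectionEvent("FGln", first_activity, 0.0)
    inj2 = InjectionEvent("FDG", second_activity, t2)
    catalog = {
        "tumor": RegionTruth("tumor", (
            OneTissueParams(K1=0.12, k2=0.2, vB=0.05),
            TwoTissueIrrevParams(K1=0.10, k2=0.10, k3=0.018, vB=0.05),
        )),
        "gray_matter": RegionTruth("gray_matter", (
            OneTissueParams(K1=0.25, k2=0.5, vB=0.04),
            TwoTissueIrrevParams(K1=0.35, k2=0.6, k3=0.06, vB=0.04),
        )),
        "kidney": RegionTruth("kidney", (
            OneTissueParams(K1=0.6, k2=0.8, vB=0.2),
            TwoTissueIrrevParams(K1=0.5, k2=0.9, k3=0.01, vB=0.2),
        )),
        "myocardium": RegionTruth("myocardium", (
            OneTissueParams(K1=0.5, k2=0.7, vB=0.3),
            TwoTissueIrrevParams(K1=0.6, k2=1.2, k3=0.05, vB=0.3),
        )),
        "muscle": RegionTruth("muscle", (
            OneTissueParams(K1=0.03, k2=0.08, vB=0.03),
            TwoTissueIrrevParams(K1=0.03, k2=0.25, k3=0.015, vB=0.03),
        )),
        "spleen": RegionTruth("spleen", (
            OneTissueParams(K1=0.8, k2=1.1, vB=0.25),
            TwoTissueIrrevParams(K1=0.9, k2=1.6, k3=0.02, vB=0.25),
        )),
    }
    names = regions if regions is not None else tuple(catalog)
    return SyntheticTruth(
        injections=(inj1, inj2),
        schedule=dual_tracer_schedule(t2=t2, end=t2 + 60.0),
        regions=tuple(catalog[n] for n in names),
        shapes=(InputShape(), InputShape()),
        body_weight=93.5,
        noise_scale=noise_scale,
        seed=seed,
    )


def default_single_truth(seed: int = 0,
                         noise_scale: float = DEFAULT_NOISE_SCALE,
                         activity: float = 263.0,
                         duration: float = 70.0) -> SyntheticTruth:
    """Full-dose single-tracer truth used for dose/duration protocol design."""
    inj = InjectionEvent("FGln", activity, 0.0)
    return SyntheticTruth(
        injections=(inj,),
        schedule=single_tracer_schedule(duration),
        regions=(RegionTruth("tumor", (OneTissueParams(K1=0.12, k2=0.2, vB=0.05),)),),
        shapes=(InputShape(),),
        body_weight=84.5,
        noise_scale=noise_scale,
        seed=seed,
    )


def simulate_tissue_tac(params, input_model: BloodInputModel,
                        schedule: FrameSchedule,
                        region_label: str = "") -> TimeActivityCurve:
    """Noiseless decay-uncorrected frame-averaged tissue curve for one tracer."""
    inj = input_model.injection
    lam = inj.decay_constant
    tmax = float(schedule.end[-1])
    grid = np.unique(np.concatenate([
        schedule.start, schedule.end, np.arange(0.0, tmax, 0.05), [0.0, tmax],
    ]))
    if isinstance(params, OneTissueParams):
        corr = evaluate_onetcm(params, input_model, grid)
    else:
        corr = evaluate_twotcm_irrev(params, input_model, grid)
    meas = corr * np.exp(-lam * np.maximum(grid - inj.injection_time, 0.0))
    values = frame_average_from_samples(grid, meas, schedule)
    return TimeActivityCurve(schedule, values, region_label=region_label,
                             decay_corrected=False)


def _blood_tac(truth: SyntheticTruth, models) -> TimeActivityCurve:
    schedule = truth.schedule
    tmax = float(schedule.end[-1])
    grid = np.unique(np.concatenate([
        schedule.start, schedule.end, np.arange(0.0, tmax, 0.05), [0.0, tmax],
    ]))
    total = np.zeros_like(grid)
    for m in models:
        total += m.measured(grid)
    values = frame_average_from_samples(grid, total, schedule)
    return TimeActivityCurve(schedule, values, region_label="blood",
                             decay_corrected=False)


def add_noise(curve: TimeActivityCurve, noise_scale: float,
              rng) -> TimeActivityCurve:
    """Add count-limited noise: ``var_i = noise_scale * C_i / dt_i``.

    Operates on decay-uncorrected values (the counts domain); negative draws
    are clipped at zero.  ``rng`` may be a Generator or an integer seed.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if curve.decay_corrected:
        raise ValueError("noise is added to decay-uncorrected curves")
    if np.any(curve.values < 0):
        raise ValueError("curve values must be non-negative")
    if noise_scale == 0:
        return curve
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma = np.sqrt(noise_scale * curve.values / curve.schedule.duration)
    noisy = np.clip(curve.values + rng.normal(size=curve.values.size) * sigma, 0.0, None)
    return curve.with_values(noisy)


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated study plus the hidden per-tracer ground-truth components.

    ``components[name][j]`` is the noiseless decay-uncorrected contribution
    of tracer ``j`` to region ``name`` (``"blood"`` for the input function).
    """

    truth: SyntheticTruth
    injections: tuple[InjectionEvent, ...]
    body_weight: float
    input_curve: TimeActivityCurve
    tissues: dict
    components: dict
    input_models: tuple[BloodInputModel, ...] = field(repr=False, default=())

    @property
    def schedule(self) -> FrameSchedule:
        return self.input_curve.schedule

    def to_dual_study(self):
        from .pipeline import DualTracerStudy

        if len(self.injections) != 2:
            raise ValueError("study has a single injection")
        return DualTracerStudy(
            injections=self.injections,
            input_curve=self.input_curve,
            tissue_curves=dict(self.tissues),
            body_weight=self.body_weight,
        )


def simulate_study(truth: SyntheticTruth) -> SimulatedStudy:
    """Simulate a (single- or dual-injection) study from a truth object.

    For two injections the schedule must contain a frame boundary at the
    second injection time so no frame straddles the tracer switch.
    """
    schedule = truth.schedule
    if len(truth.injections) == 2:
        t2 = truth.injections[1].injection_time
        if not truth.injections[1].injection_time > truth.injections[0].injection_time:
            raise ValueError("second injection must follow the first")
        boundaries = np.concatenate([schedule.start, schedule.end[-1:]])
        if not np.any(np.abs(boundaries - t2) < 1e-9):
            raise ValueError("schedule lacks a frame boundary at the second injection")
    models = tuple(generate_input_function(inj, shape)
                   for inj, shape in zip(truth.injections, truth.shapes))
    components: dict = {"blood": []}
    for j, m in enumerate(models):
        comp = _blood_tac(truth, [m])
        components["blood"].append(comp)
    blood_clean = _blood_tac(truth, models)
    input_curve = add_noise(blood_clean, truth.noise_scale, truth.rng_for("noise/blood"))

    tissues = {}
    for region in truth.regions:
        comps = []
        total = np.zeros(schedule.n_frames)
        for j, m in enumerate(models):
            p = region.params[j]
            if p is None:
                comps.append(TimeActivityCurve(schedule, np.zeros(schedule.n_frames),
                                               region_label=region.name))
            else:
                tac = simulate_tissue_tac(p, m, schedule, region_label=region.name)
                comps.append(tac)
            total += comps[-1].values
        components[region.name] = comps
        clean = TimeActivityCurve(schedule, total, region_label=region.name,
                                  decay_corrected=False)
        tissues[region.name] = add_noise(clean, truth.noise_scale,
                                         truth.rng_for(f"noise/{region.name}"))
    return SimulatedStudy(
        truth=truth,
        injections=truth.injections,
        body_weight=truth.body_weight,
        input_curve=input_curve,
        tissues=tissues,
        components=components,
        input_models=models,
    )


def truth_from_yaml(path) -> SyntheticTruth:
    """Build a dual-tracer truth from a small YAML override file.

    Recognised keys (all optional): ``seed``, ``noise_scale``,
    ``first_activity_mbq``, ``second_activity_mbq``, ``second_injection_min``,
    ``regions`` (list of region names from the built-in catalogue).
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return default_dual_truth(
        seed=int(doc.get("seed", 0)),
        noise_scale=float(doc.get("noise_scale", DEFAULT_NOISE_SCALE)),
        first_activity=float(doc.get("first_activity_mbq", 41.0)),
        second_activity=float(doc.get("second_activity_mbq", 394.0)),
        t2=float(doc.get("second_injection_min", 29.0)),
        regions=tuple(doc["regions"]) if "regions" in doc else None,
    )


def simulate_dual_tracer_study(truth: SyntheticTruth):
    """Simulate a dual-tracer study; returns ``(DualTracerStudy, SimulatedStudy)``."""
    sim = simulate_study(truth)
    return sim.to_dual_study(), sim


def _thin_curve(curve: TimeActivityCurve, fraction: float, noise_scale: float,
                rng: np.random.Generator) -> TimeActivityCurve:
    if noise_scale == 0 or fraction == 1.0:
        return curve
    extra_var = noise_scale * curve.values / curve.schedule.duration * (1.0 / fraction - 1.0)
    noisy = curve.values + rng.normal(size=curve.values.size) * np.sqrt(extra_var)
    return curve.with_values(np.clip(noisy, 0.0, None))


def thin_dose(obj, fraction: float, seed: int,
              noise_scale: float | None = None):
    """Emulate list-mode subsampling to ``fraction`` of the injected dose.

    The expected (renormalised) signal is unchanged; the count-limited noise
    is regenerated at the thinned count level (variance scaled by
    ``1/fraction``), realised by adding independent noise with the variance
    increment.  Injected-activity metadata are scaled by ``fraction``.
    Accepts a TimeActivityCurve or a SimulatedStudy.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return obj
    if isinstance(obj, TimeActivityCurve):
        scale = DEFAULT_NOISE_SCALE if noise_scale is None else noise_scale
        return _thin_curve(obj, fraction, scale, np.random.default_rng(seed))
    if isinstance(obj, SimulatedStudy):
        scale = obj.truth.noise_scale if noise_scale is None else noise_scale
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])
        new_inj = tuple(
            replace(inj, injected_activity=inj.injected_activity * fraction)
            for inj in obj.injections
        )
        tissues = {name: _thin_curve(tac, fraction, scale, rng)
                   for name, tac in obj.tissues.items()}
        input_curve = _thin_curve(obj.input_curve, fraction, scale, rng)
        return replace(obj, injections=new_inj, input_curve=input_curve,
                       tissues=tissues)
    raise TypeError("thin_dose accepts a TimeActivityCurve or SimulatedStudy")
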
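import numpy as np
import pytest

from dualtracer.fitting import FitOptions
from dualtracer.kinetics import (
    InjectionEvent,
    OneTissueParams,
    TimeActivityCurve,
    TwoTissueIrrevParams,
    decay_correct,
    frame_average_from_samples,
)
from dualtracer.simulate import (
    generate_input_function,
    simulate_tissue_tac,
    single_tracer_schedule,
)


@pytest.fixture
def fast_options():
    """Fit options matched to the generator: it applies no input delay, so a
    single delay-grid point keeps the many fit-based tests quick."""
    return FitOptions(delay_grid=(0.0,))


@pytest.fixture(scope="session")
def fgln_injection():
    return InjectionEvent("FGln", 41.0, 0.0)


@pytest.fixture(scope="session")
def fdg_injection():
    return InjectionEvent("FDG", 394.0, 0.0)


def make_single_tracer_pair(injection, params, duration=70.0, decay_ref=None):
    """Noiseless (tissue, blood) decay-corrected TAC pair for one tracer."""
    model = generate_input_function(injection)
    sched = single_tracer_schedule(duration)
    tissue = simulate_tissue_tac(params, model, sched, "tissue")
    grid = np.unique(np.concatenate([
        sched.start, sched.end, np.arange(0.0, duration, 0.05)]))
    blood = TimeActivityCurve(
        sched, frame_average_from_samples(grid, model.measured(grid), sched), "blood")
    ref = injection.injection_time if decay_ref is None else decay_ref
    return (decay_correct(tissue, injection.half_life, ref),
            decay_correct(blood, injection.half_life, ref))


@pytest.fixture(scope="session")
def onetcm_pair(fgln_injection):
    """Noiseless reversible-tracer pair, truth V_T = 0.6 (vB = 0)."""
    return make_single_tracer_pair(
        fgln_injection, OneTissueParams(K1=0.12, k2=0.2, vB=0.0))


@pytest.fixture(scope="session")
def twotcm_pair(fdg_injection):
    """Noiseless irreversible-tracer pair, truth K_i = 1/60 (vB = 0)."""
    return make_single_tracer_pair(
        fdg_injection, TwoTissueIrrevParams(K1=0.1, k2=0.1, k3=0.02, vB=0.0))
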
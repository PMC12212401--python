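"""Parameter estimation for compartment models and input-function tails.

Two estimation routes are provided for the same models:

``fit_compartment``
    Classical nonlinear weighted least squares (Levenberg-Marquardt style,
    via :func:`scipy.optimize.least_squares`) over all micro-parameters, with
    the input-to-tissue delay handled on a discrete grid.

``fit_separable``
    Separable-parameter-space estimation: the linear coefficients (uptake
    amplitudes and the blood fraction) are solved directly by bounded linear
    least squares at each value of the single nonlinear rate (k2 for the
    1TCM; theta = k2+k3 for the irreversible 2TCM), so the nonlinear search
    is one-dimensional.  This is the reformulation used by dedicated
    dual-tracer fitting software and is much faster and less prone to local
    minima than the full nonlinear fit.

``fit_triexponential``
    Multistart variable-projection fit of a sum of three decaying
    exponentials to the post-peak portion of a blood curve; used to project
    a first tracer's input function beyond its measured window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, lsq_linear, minimize_scalar, nnls

from .kinetics import (
    F18_HALF_LIFE_MIN,
    FrameSchedule,
    OneTissueParams,
    TimeActivityCurve,
    TriexpParams,
    TwoTissueIrrevParams,
    _as_continuous,
    average_preserving_interpolant,
    exp_conv,
)

__all__ = ["FitOptions", "FitResult", "FrameIntegrator", "fit_compartment",
           "fit_separable", "fit_triexponential"]


@dataclass
class FitOptions:
    """Settings shared by the compartment-fitting routines.

    weighting
        ``"duration-decay"`` uses ``w_i = dt_i * exp(-lambda t_i)`` (an
        approximate inverse-variance weight for decay-corrected data);
        ``"uniform"`` uses equal weights.
    delay_grid
        Candidate input-to-tissue delays in minutes; the other parameters
        are re-fit at each grid point and the best point wins.
    bounds / init
        Per-parameter box bounds and initial values for the nonlinear fit.
    strategy
        ``"grid"`` uses the exhaustive nonlinear-parameter grid only;
        ``"grid-refine"`` polishes the best grid point with a bounded 1-D
        search.
    """

    weighting: str = "duration-decay"
    half_life: float = F18_HALF_LIFE_MIN
    delay_grid: tuple = tuple(np.round(np.arange(-1.0, 2.0001, 0.1), 3))
    bounds: dict = field(default_factory=lambda: {
        "K1": (0.0, 5.0), "k2": (1e-4, 5.0), "k3": (0.0, 5.0), "vB": (0.0, 0.5),
    })
    init: dict = field(default_factory=lambda: {
        "K1": 0.1, "k2": 0.1, "k3": 0.01, "vB": 0.05,
    })
    strategy: str = "grid-refine"
    n_grid: int = 48
    seed: int = 0

    def weights(self, schedule: FrameSchedule) -> np.ndarray:
        if self.weighting == "uniform":
            return np.ones(schedule.n_frames)
        if self.weighting == "duration-decay":
            lam = math.log(2.0) / self.half_life
            return schedule.duration * np.exp(-lam * schedule.mid)
        raise ValueError(f"unknown weighting scheme {self.weighting!r}")


@dataclass
class FitResult:
    """Outcome of a fit: parameters, weighted RSS, SEs and bookkeeping."""

    params: object
    objective: float
    param_se: dict
    converged: bool
    n_iter: int
    method_tag: str
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        p = self.params
        d = {
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "method": self.method_tag,
            "params": {k: float(v) for k, v in vars(p).items()}
            if not isinstance(p, TriexpParams)
            else {"amplitudes": list(p.amplitudes), "rates": list(p.rates),
                  "onset_time": p.onset_time},
            "param_se": {k: float(v) for k, v in self.param_se.items()},
        }
        if isinstance(p, OneTissueParams):
            d["VT"] = p.vt
        elif isinstance(p, TwoTissueIrrevParams):
            d["Ki"] = p.ki
        return d


class FrameIntegrator:
    """Precomputed trapezoid weights mapping dense samples to frame means.

    The sample grid must contain every frame boundary; frame averages then
    reduce to a single matrix-vector product, which keeps the inner loop of
    the separable search cheap.
    """

    def __init__(self, grid: np.ndarray, schedule: FrameSchedule):
        grid = np.asarray(grid, dtype=float)
        m, n = schedule.n_frames, grid.size
        W = np.zeros((m, n))
        for i, (s, e) in enumerate(zip(schedule.start, schedule.end)):
            i0 = int(np.searchsorted(grid, s - 1e-9))
            i1 = int(np.searchsorted(grid, e - 1e-9))
            if abs(grid[i0] - s) > 1e-6 or abs(grid[i1] - e) > 1e-6:
                raise ValueError("grid must contain all frame boundaries")
            h = np.diff(grid[i0 : i1 + 1])
            w = np.zeros(i1 - i0 + 1)
            w[:-1] += 0.5 * h
            w[1:] += 0.5 * h
            W[i, i0 : i1 + 1] = w / (e - s)
        self.W = W
        self.grid = grid

    def __call__(self, samples: np.ndarray) -> np.ndarray:
        return self.W @ samples


def _input_interpolant(input_curve):
    """Continuous input for fitting: average-preserving reconstruction for
    framed blood curves, pass-through for already-continuous models."""
    if isinstance(input_curve, TimeActivityCurve):
        return average_preserving_interpolant(input_curve)
    return _as_continuous(input_curve)


def _check_states(tissue: TimeActivityCurve, input_curve: TimeActivityCurve):
    if tissue.decay_corrected != input_curve.decay_corrected:
        raise ValueError("tissue and input must share a decay-correction state")
    if tissue.decay_corrected:
        if abs(tissue.decay_reference_time - input_curve.decay_reference_time) > 1e-6:
            raise ValueError("tissue and input decay references differ")


def _setup(cp_cont, schedule: FrameSchedule, delay: float):
    """Dense grid covering [0, scan end] with frame boundaries included."""
    tmax = float(schedule.end[-1])
    parts = [np.asarray([0.0, tmax]), schedule.start, schedule.end,
             np.arange(0.0, tmax, 0.05)]
    knots = getattr(cp_cont, "t", None)
    if knots is not None:
        shifted = np.asarray(knots) + delay
        parts.append(shifted[(shifted > 0) & (shifted < tmax)])
    else:
        parts.append(np.arange(0.0, min(3.0, tmax), 0.01))
    grid = np.unique(np.concatenate(parts))
    g = np.asarray(cp_cont(grid - delay), dtype=float)
    return grid, g, FrameIntegrator(grid, schedule)


def _frame_model(kind: str, x: np.ndarray, grid, g, integ) -> np.ndarray:
    if kind == "1tcm":
        K1, k2, vB = x
        samples = (1.0 - vB) * K1 * exp_conv(grid, g, k2) + vB * g
    else:
        K1, k2, k3, vB = x
        theta = k2 + k3
        tissue = K1 * (k3 / theta * exp_conv(grid, g, 0.0)
                       + k2 / theta * exp_conv(grid, g, theta))
        samples = (1.0 - vB) * tissue + vB * g
    return integ(samples)


def _normalise_kind(model_kind: str) -> str:
    kind = model_kind.lower().replace("_", "-")
    if kind in ("1tcm", "onetcm", "1-tissue"):
        return "1tcm"
    if kind in ("2tcm-irrev", "2tcm", "twotcm-irrev", "2-tissue-irrev"):
        return "2tcm"
    raise ValueError(f"unknown model kind {model_kind!r}")


def _param_se(kind, x, grid, g, integ, y, w, objective) -> dict:
    """Standard errors from the local curvature of the weighted objective."""
    names = ["K1", "k2", "vB"] if kind == "1tcm" else ["K1", "k2", "k3", "vB"]
    n, p = y.size, len(x)
    if n <= p:
        return {k: float("nan") for k in names}
    J = np.empty((n, p))
    for j in range(p):
        h = max(1e-6, 1e-4 * abs(x[j]))
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] = max(xm[j] - h, 1e-12 if names[j] == "k2" else 0.0)
        J[:, j] = (_frame_model(kind, xp, grid, g, integ)
                   - _frame_model(kind, xm, grid, g, integ)) / (xp[j] - xm[j])
    sw = np.sqrt(w)
    Jw = J * sw[:, None]
    sigma2 = objective / (n - p)
    try:
        cov = sigma2 * np.linalg.inv(Jw.T @ Jw)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se))


def _make_params(kind, x, delay):
    if kind == "1tcm":
        return OneTissueParams(K1=float(x[0]), k2=float(max(x[1], 1e-8)),
                               vB=float(min(x[2], 1 - 1e-12)), delay=float(delay))
    return TwoTissueIrrevParams(K1=float(x[0]), k2=float(max(x[1], 1e-8)),
                                k3=float(max(x[2], 0.0)),
                                vB=float(min(x[3], 1 - 1e-12)), delay=float(delay))


def fit_compartment(model_kind: str, tissue: TimeActivityCurve,
                    input_curve: TimeActivityCurve,
                    options: FitOptions | None = None) -> FitResult:
    """Nonlinear weighted least-squares compartment fit.

    The delay is searched over ``options.delay_grid``; at each candidate the
    remaining parameters are fit by bounded Levenberg-Marquardt-type
    iteration, and the grid point with the lowest weighted residual sum of
    squares wins.  Non-convergence at every delay is reported through the
    ``converged`` flag rather than an exception.
    """
    options = options or FitOptions()
    kind = _normalise_kind(model_kind)
    _check_states(tissue, input_curve)
    y = tissue.values
    schedule = tissue.schedule
    w = options.weights(schedule)
    sw = np.sqrt(w)
    cp_cont = _input_interpolant(input_curve)
    b = options.bounds
    if kind == "1tcm":
        lb = np.array([b["K1"][0], b["k2"][0], b["vB"][0]])
        ub = np.array([b["K1"][1], b["k2"][1], b["vB"][1]])
        x0 = np.array([options.init["K1"], options.init["k2"], options.init["vB"]])
    else:
        lb = np.array([b["K1"][0], b["k2"][0], b["k3"][0], b["vB"][0]])
        ub = np.array([b["K1"][1], b["k2"][1], b["k3"][1], b["vB"][1]])
        x0 = np.array([options.init["K1"], options.init["k2"],
                       options.init["k3"], options.init["vB"]])
    x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)

    best = None
    total_nfev = 0
    any_converged = False
    for delay in options.delay_grid:
        grid, g, integ = _setup(cp_cont, schedule, delay)

        def resid(x):
            return sw * (_frame_model(kind, x, grid, g, integ) - y)

        res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        total_nfev += res.nfev
        obj = float(2.0 * res.cost)
        ok = res.status > 0
        any_converged = any_converged or ok
        if best is None or obj < best[0]:
            best = (obj, res.x.copy(), delay, grid, g, integ)
    obj, x, delay, grid, g, integ = best
    params = _make_params(kind, x, delay)
    se = _param_se(kind, x, grid, g, integ, y, w, obj)
    return FitResult(params=params, objective=obj, param_se=se,
                     converged=any_converged, n_iter=total_nfev, method_tag="lm")


def _solve_linear(A: np.ndarray, y: np.ndarray, sw: np.ndarray, vb_ub: float):
    """Bounded weighted linear LS; last column is the blood-fraction basis."""
    Aw = A * sw[:, None]
    yw = y * sw
    ub = np.full(A.shape[1], np.inf)
    ub[-1] = vb_ub
    res = lsq_linear(Aw, yw, bounds=(np.zeros(A.shape[1]), ub), method="bvls")
    return res.x, float(res.cost * 2.0)


def fit_separable(model_kind: str, tissue: TimeActivityCurve,
                  input_curve: TimeActivityCurve,
                  options: FitOptions | None = None) -> FitResult:
    """Separable-parameter-space compartment fit.

    For the 1TCM the only nonlinear parameter is ``k2``: the basis curves
    ``{exp(-k2 t) (x) Cp, Cb}`` yield ``(1-vB) K1`` and ``vB`` by bounded
    linear least squares.  For the 2TCM-irrev the nonlinear parameter is
    ``theta = k2 + k3`` with basis ``{int Cp, exp(-theta t) (x) Cp, Cb}``
    and coefficients ``alpha1, alpha2, vB`` mapping back to
    ``K1 = (a1+a2)/(1-vB)``, ``k3 = theta a1/(a1+a2)``,
    ``k2 = theta a2/(a1+a2)`` and ``K_i = a1/(1-vB)``.  Negative linear
    coefficients are precluded by the non-negativity bounds.
    """
    options = options or FitOptions()
    kind = _normalise_kind(model_kind)
    _check_states(tissue, input_curve)
    y = tissue.values
    schedule = tissue.schedule
    w = options.weights(schedule)
    sw = np.sqrt(w)
    cp_cont = _input_interpolant(input_curve)
    vb_ub = options.bounds["vB"][1]
    if kind == "1tcm":
        rate_lo = max(options.bounds["k2"][0], 1e-3)
        rate_hi = options.bounds["k2"][1]
    else:
        rate_lo = max(options.bounds["k2"][0], 1e-3)
        rate_hi = options.bounds["k2"][1] + options.bounds["k3"][1]
    rate_grid = np.geomspace(rate_lo, rate_hi, options.n_grid)

    best = None  # (obj, coeffs, rate, delay, setup...)
    n_eval = 0
    for delay in options.delay_grid:
        grid, g, integ = _setup(cp_cont, schedule, delay)
        Bb = integ(g)
        cum = integ(exp_conv(grid, g, 0.0)) if kind == "2tcm" else None

        def objective(rate):
            nonlocal n_eval
            n_eval += 1
            Bexp = integ(exp_conv(grid, g, rate))
            A = (np.column_stack([Bexp, Bb]) if kind == "1tcm"
                 else np.column_stack([cum, Bexp, Bb]))
            c, obj = _solve_linear(A, y, sw, vb_ub)
            return obj, c

        local_best = None
        for rate in rate_grid:
            obj, c = objective(rate)
            if local_best is None or obj < local_best[0]:
                local_best = (obj, c, rate)
        if options.strategy == "grid-refine":
            idx = int(np.searchsorted(rate_grid, local_best[2]))
            lo = rate_grid[max(idx - 1, 0)]
            hi = rate_grid[min(idx + 1, rate_grid.size - 1)]
            if hi > lo:
                res = minimize_scalar(lambda lr: objective(math.exp(lr))[0],
                                      bounds=(math.log(lo), math.log(hi)),
                                      method="bounded",
                                      options={"xatol": 1e-8})
                obj, c = objective(math.exp(res.x))
                if obj < local_best[0]:
                    local_best = (obj, c, math.exp(res.x))
        if best is None or local_best[0] < best[0]:
            best = (*local_best, delay, grid, g, integ)

    obj, c, rate, delay, grid, g, integ = best
    flagged = False
    if kind == "1tcm":
        vB = float(c[1])
        K1 = float(c[0] / (1.0 - vB)) if vB < 1 else float(c[0])
        x = np.array([K1, rate, vB])
    else:
        a1, a2, vB = float(c[0]), float(c[1]), float(c[2])
        s = a1 + a2
        if s <= 1e-12:
            flagged = True
            x = np.array([0.0, rate, 0.0, vB])
        else:
            K1 = s / (1.0 - vB)
            k3 = rate * a1 / s
            k2 = rate * a2 / s
            x = np.array([K1, k2, k3, vB])
    params = _make_params(kind, x, delay)
    se = _param_se(kind, x, grid, g, integ, y, w, obj)
    tag = "separable-grid" if options.strategy == "grid" else "separable-lm"
    return FitResult(params=params, objective=obj, param_se=se,
                     converged=not flagged, n_iter=n_eval, method_tag=tag,
                     extras={"nonlinear_rate": float(rate)})


# ---------------------------------------------------------------------------
# Triexponential input-function tail fit
# ---------------------------------------------------------------------------


def fit_triexponential(input_curve: TimeActivityCurve, fit_start: float,
                       n_starts: int = 8, seed: int = 0) -> FitResult:
    """Fit ``sum_i A_i exp(-L_i (t - t0))`` to post-peak blood frames.

    Only frames whose mid-time is at or after ``fit_start`` enter the fit
    (at least 7 required); ``t0`` is anchored at the first used mid-time.
    Rates are searched from ``n_starts`` log-spaced multistart triples with
    amplitudes solved by non-negative least squares at each step (variable
    projection), and the best run is polished by bounded nonlinear least
    squares on the log-rates.
    """
    sched = input_curve.schedule
    mask = sched.mid >= fit_start
    if mask.sum() < 7:
        raise ValueError("fewer than 7 post-peak frames: triexponential fit under-determined")
    t0 = float(sched.start[mask][0])
    a = sched.start[mask] - t0
    b = sched.end[mask] - t0
    y = input_curve.values[mask]

    if np.allclose(y, 0.0):
        params = TriexpParams((0.0, 0.0, 0.0), (1.0, 0.1, 0.01), onset_time=t0)
        return FitResult(params=params, objective=0.0,
                         param_se={f"A{i}": 0.0 for i in (1, 2, 3)},
                         converged=True, n_iter=0, method_tag="triexp",
                         extras={"fit_start": fit_start})

    def basis(rates):
        # exact frame average of exp(-L (t - t0)) over [a, b]: the data are
        # frame means, so the model must be compared as frame means too
        rates = np.asarray(rates, dtype=float)
        ea = np.exp(-np.outer(a, rates))
        eb = np.exp(-np.outer(b, rates))
        return (ea - eb) / (rates[None, :] * (b - a)[:, None])

    def amps_for(rates):
        amp, _ = nnls(basis(rates), y)
        return amp

    def resid_log(z):
        rates = np.exp(z)
        B = basis(rates)
        amp, _ = nnls(B, y)
        return B @ amp - y

    rng = np.random.default_rng(seed)
    starts = [np.array([1.0, 0.1, 0.01])]
    while len(starts) < n_starts:
        starts.append(np.array([
            math.exp(rng.uniform(math.log(0.2), math.log(5.0))),
            math.exp(rng.uniform(math.log(0.02), math.log(0.5))),
            math.exp(rng.uniform(math.log(0.002), math.log(0.05))),
        ]))

    best = None
    total_nfev = 0
    lb, ub = math.log(1e-4), math.log(20.0)
    for rates0 in starts:
        z0 = np.clip(np.log(rates0), lb, ub)
        res = least_squares(resid_log, z0, bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, max_nfev=200)
        total_nfev += res.nfev
        obj = float(2.0 * res.cost)
        if best is None or obj < best[0]:
            best = (obj, np.exp(res.x), res.status > 0)
    obj, rates, ok = best
    amps = amps_for(rates)
    order = np.argsort(rates)[::-1]  # fast component first
    rates = rates[order]
    amps = amps[order]
    params = TriexpParams(tuple(amps), tuple(rates), onset_time=t0)
    return FitResult(params=params, objective=obj,
                     param_se={}, converged=bool(ok), n_iter=total_nfev,
                     method_tag="triexp", extras={"fit_start": fit_start})
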
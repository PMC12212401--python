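"""Logan and Patlak graphical estimators with t* selection.

Both estimators linearise the compartment-model equations so that the
macro-parameter of interest appears as an asymptotic slope:

* Logan (reversible tracers): ``int_0^t C_T / C_T(t)`` against
  ``int_0^t Cp / C_T(t)``; the late slope estimates ``V_T``.
* Patlak (irreversible tracers): ``C_T / Cp`` against
  ``int_0^t Cp / Cp``; the late slope estimates ``K_i``.

Cumulative integrals use the trapezoid rule over frame mid-times with a
virtual zero anchor at t = 0.  The blood-fraction contribution is not
subtracted before regression (plain application to measured curves), which
mirrors common practice in clinical kinetic-analysis software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .kinetics import TimeActivityCurve

__all__ = ["GraphicalResult", "logan_vt", "patlak_ki", "select_tstar",
           "graphical_plot_table"]

#: Default start of the linear segment (minutes post-injection).
DEFAULT_TSTAR_LOGAN = 15.0
DEFAULT_TSTAR_PATLAK = 20.0


@dataclass(frozen=True)
class GraphicalResult:
    """Slope/intercept of the linearised plot; the slope is the estimate."""

    slope: float
    intercept: float
    t_star: float
    n_points_used: int
    r_squared: float
    estimate_kind: str  # "VT" or "Ki"

    @property
    def estimate(self) -> float:
        return self.slope


def _cumint(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid with a (t=0, 0) anchor, evaluated at t."""
    if t[0] > 0:
        tt = np.concatenate([[0.0], t])
        vv = np.concatenate([[0.0], v])
        return cumulative_trapezoid(vv, tt, initial=0.0)[1:]
    return cumulative_trapezoid(v, t, initial=0.0)


def _check_pair(tissue: TimeActivityCurve, input_curve: TimeActivityCurve):
    if tissue.decay_corrected != input_curve.decay_corrected:
        raise ValueError("tissue and input must share a decay-correction state")
    if tissue.decay_corrected:
        if abs(tissue.decay_reference_time - input_curve.decay_reference_time) > 1e-6:
            raise ValueError("tissue and input decay references differ")
    if tissue.schedule.n_frames != input_curve.schedule.n_frames or not np.allclose(
        tissue.schedule.mid, input_curve.schedule.mid
    ):
        raise ValueError("tissue and input must share one frame schedule")


def _points(kind: str, tissue: TimeActivityCurve, input_curve: TimeActivityCurve):
    t = tissue.schedule.mid
    ct = tissue.values
    cp = input_curve.values
    int_ct = _cumint(t, ct)
    int_cp = _cumint(t, cp)
    if kind == "logan":
        with np.errstate(divide="ignore", invalid="ignore"):
            x = int_cp / ct
            y = int_ct / ct
        valid = ct > 0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = int_cp / cp
            y = ct / cp
        valid = cp > 0
    return t, x, y, valid


def _regress(kind: str, tissue, input_curve, t_star: float) -> tuple:
    _check_pair(tissue, input_curve)
    t, x, y, valid = _points(kind, tissue, input_curve)
    use = (t >= t_star) & valid
    if use.sum() < 3:
        raise ValueError(f"fewer than 3 usable frames beyond t* = {t_star} min")
    if not valid[t >= t_star].all():
        raise ValueError("non-positive denominator values beyond t*")
    res = stats.linregress(x[use], y[use])
    return res, x, y, use


def logan_vt(tissue: TimeActivityCurve, input_curve: TimeActivityCurve,
             t_star: float = DEFAULT_TSTAR_LOGAN) -> GraphicalResult:
    """Logan plot over frames with mid-time >= t*; slope reported as V_T."""
    res, _, _, use = _regress("logan", tissue, input_curve, t_star)
    return GraphicalResult(slope=float(res.slope), intercept=float(res.intercept),
                           t_star=float(t_star), n_points_used=int(use.sum()),
                           r_squared=float(res.rvalue**2), estimate_kind="VT")


def patlak_ki(tissue: TimeActivityCurve, input_curve: TimeActivityCurve,
              t_star: float = DEFAULT_TSTAR_PATLAK) -> GraphicalResult:
    """Patlak plot over frames with mid-time >= t*; slope reported as K_i."""
    res, _, _, use = _regress("patlak", tissue, input_curve, t_star)
    return GraphicalResult(slope=float(res.slope), intercept=float(res.intercept),
                           t_star=float(t_star), n_points_used=int(use.sum()),
                           r_squared=float(res.rvalue**2), estimate_kind="Ki")


def select_tstar(tissue: TimeActivityCurve, input_curve: TimeActivityCurve,
                 estimator: str = "logan", max_rel_error: float = 0.10) -> float:
    """Earliest t* whose late points all lie within ``max_rel_error`` of the line.

    Candidates are frame mid-times leaving at least three points; for each,
    the regression is refit and the largest relative deviation of the used
    points from the fitted line is checked.  If no candidate satisfies the
    criterion the latest feasible t* is returned with a warning.
    """
    kind = estimator.lower()
    if kind not in ("logan", "patlak"):
        raise ValueError("estimator must be 'logan' or 'patlak'")
    _check_pair(tissue, input_curve)
    t, x, y, valid = _points(kind, tissue, input_curve)
    candidates = [tm for tm in t if ((t >= tm) & valid).sum() >= 3]
    last_feasible = None
    for tm in candidates:
        use = (t >= tm) & valid
        if not valid[t >= tm].all():
            continue
        res = stats.linregress(x[use], y[use])
        yhat = res.slope * x[use] + res.intercept
        denom = np.where(np.abs(yhat) > 0, np.abs(yhat), np.inf)
        dev = np.max(np.abs(y[use] - yhat) / denom)
        last_feasible = float(tm)
        if dev < max_rel_error:
            return float(tm)
    warnings.warn("t* criterion never met; returning latest feasible t*")
    if last_feasible is None:
        raise ValueError("no feasible t* (insufficient usable frames)")
    return last_feasible


def graphical_plot_table(kind: str, tissue: TimeActivityCurve,
                         input_curve: TimeActivityCurve,
                         t_star: float) -> pd.DataFrame:
    """Per-point plot data (x, y, used flag) for figure regeneration."""
    kind = kind.lower()
    _check_pair(tissue, input_curve)
    t, x, y, valid = _points(kind, tissue, input_curve)
    use = (t >= t_star) & valid
    return pd.DataFrame({"mid_time_min": t, "x": x, "y": y,
                         "used": use, "valid": valid})
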
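"""One-tissue compartment model: forward simulation and weighted fitting.

Model
-----
Tissue tracer concentration follows

    dC_T/dt = K1 * Cp(t) - k2 * C_T(t),    C_T(0) = 0

so ``C_T(t) = K1 * INT_0^t Cp(s) exp(-k2 (t - s)) ds``.  The measured VOI
signal additionally contains an arterial blood-volume fraction Va:

    C_meas(t) = (1 - Va) * C_T(t) + Va * Cb(t)          ("standard")
    C_meas(t) = C_T(t) + Va * Cb(t)                     ("additive")

with Cp plasma and Cb whole-blood concentration.  The total volume of
distribution is VT = K1 / k2, the equilibrium tissue-to-plasma ratio.

Numerics
--------
The input function is treated as piecewise linear between its samples (zero
before the first sample), for which the convolution with ``exp(-k2 t)`` has
an exact per-segment recursion — no quadrature in the fitting loop.  Frame
predictions are exact time-averages over each frame, using the identity
``INT y dt = (INT Cp dt - dy) / k2`` that follows from the ODE, so frame
integration introduces no additional discretisation error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .input_function import InputFunction, resample_input
from .tac_core import FrameSchedule, TimeActivityCurve

VA_STANDARD = "standard"
VA_ADDITIVE = "additive"

#: Parameter bounds for the bounded least-squares fit: (K1, k2, Va).
DEFAULT_BOUNDS = ((0.0, 1e-4, 0.0), (5.0, 5.0, 1.0))

#: Multi-start initial grid (K1 x k2 x Va), deterministic order.
DEFAULT_START_GRID = tuple(
    product((0.01, 0.1, 1.0), (0.01, 0.1, 1.0), (0.05, 0.3))
)


@dataclass(frozen=True)
class KineticParams:
    """One-tissue-compartment parameters.

    k1 : ml plasma / min / ml tissue — plasma-to-tissue transfer.
    k2 : 1 / min — tissue-to-plasma efflux.
    va : ml blood / ml tissue — arterial blood-volume fraction in the signal.
    """

    k1: float
    k2: float
    va: float = 0.0

    def __post_init__(self):
        if self.k1 < 0:
            raise ValidationError("K1 must be >= 0")
        if not (self.k2 > 0):
            raise ValidationError("k2 must be > 0")
        if not (0.0 <= self.va <= 1.0):
            raise ValidationError("Va must lie in [0, 1]")

    @property
    def vt(self) -> float:
        return self.k1 / self.k2

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.va])


def compute_vt(params: KineticParams) -> float:
    """Total volume of distribution, VT = K1 / k2."""
    if not (params.k2 > 0):
        raise ValidationError("VT requires k2 > 0")
    return params.k1 / params.k2


def _pwl_exp_response(t: np.ndarray, cp: np.ndarray, k2: float) -> np.ndarray:
    """``y(t_j) = INT_0^{t_j} cp(s) exp(-k2 (t_j - s)) ds`` for piecewise-linear cp.

    Exact per-segment solution; ``t`` must start at 0 with ``cp[0]`` the
    value there.  The first-order recurrence ``y[j+1] = E_j y[j] + g_j``
    (``E_j = exp(-k2 dt_j)``, ``g_j`` the exact segment integral) is
    evaluated in vectorised windows whose accumulated exponent stays below
    50, which keeps the rescaled cumulative sums inside float64 range for
    any k2.  expm1 keeps small-``k2*dt`` segments accurate.
    """
    n = t.size
    y = np.zeros(n)
    if n < 2:
        return y
    dt = np.diff(t)
    x = k2 * dt
    E = np.exp(-x)
    em = -np.expm1(-x)  # 1 - E, accurate for small x
    b = np.diff(cp) / dt
    g = (cp[:-1] + b * dt) * em / k2 - b * (em - x * E) / (k2 * k2)
    start = 0
    while start < n - 1:
        cx = np.cumsum(x[start:])
        end = start + int(np.searchsorted(cx, 50.0)) + 1
        end = min(max(end, start + 1), n - 1)
        if end - start == 1:
            y[start + 1] = y[start] * E[start] + g[start]
            start = end
            continue
        sl = slice(start, end)
        ex = np.concatenate(([0.0], np.cumsum(x[sl])))  # k2 (t_j - t_start)
        s = np.concatenate(([0.0], np.cumsum(g[sl] * np.exp(ex[1:]))))
        y[start : end + 1] = np.exp(-ex) * (y[start] + s)
        start = end
    return y


def _support_grid(aif: InputFunction, extra: np.ndarray, t_max: float) -> np.ndarray:
    """Merged knot grid on [0, t_max] for exact piecewise-linear evaluation.

    The input is zero before its first sample; when that sample sits after
    t=0 a knot is inserted immediately below it so the step (rather than a
    ramp from injection) is represented in the piecewise-linear basis.
    """
    knots = np.union1d(
        aif.times_min[aif.times_min <= t_max + 1e-12],
        np.concatenate(([0.0], np.atleast_1d(extra))),
    )
    knots = knots[(knots >= 0.0) & (knots <= t_max + 1e-12)]
    t0 = aif.times_min[0]
    if t0 > 0.0:
        step = t0 - max(1e-12, 1e-12 * t0)
        if step > 0.0:
            knots = np.union1d(knots, [step])
    return knots


class _FramePredictor:
    """Pre-computed grids for repeated frame predictions on one (AIF, schedule).

    Building the merged knot grid and the blood/plasma interpolants once and
    reusing them per candidate parameter vector keeps the fit loop cheap.
    """

    def __init__(self, aif: InputFunction, schedule: FrameSchedule, hold_last: bool = False):
        ends = schedule.end_min
        knots = _support_grid(
            aif, np.concatenate((schedule.start_min, ends)), ends[-1]
        )
        res = resample_input(aif, knots, hold_last=hold_last)
        self.t = knots
        self.cp = res.cp
        self.cb = res.cb
        dt = np.diff(knots)
        self._icp = np.concatenate(([0.0], np.cumsum(0.5 * (self.cp[1:] + self.cp[:-1]) * dt)))
        self._icb = np.concatenate(([0.0], np.cumsum(0.5 * (self.cb[1:] + self.cb[:-1]) * dt)))
        self._i_start = np.searchsorted(knots, schedule.start_min)
        self._i_end = np.searchsorted(knots, ends)
        self.durations = schedule.duration_min

    def frame_means(self, k1: float, k2: float, va: float, formulation: str) -> np.ndarray:
        y = _pwl_exp_response(self.t, self.cp, k2)
        iy = (self._icp - y) / k2  # cumulative INT_0^t y, exact via the ODE
        d_iy = iy[self._i_end] - iy[self._i_start]
        d_icb = self._icb[self._i_end] - self._icb[self._i_start]
        if formulation == VA_STANDARD:
            total = (1.0 - va) * k1 * d_iy + va * d_icb
        elif formulation == VA_ADDITIVE:
            total = k1 * d_iy + va * d_icb
        else:
            raise ValidationError(f"unknown Va formulation {formulation!r}")
        return total / self.durations


def model_tissue_curve(
    params: KineticParams,
    aif: InputFunction,
    times,
    va_formulation: str = VA_STANDARD,
    hold_last: bool = False,
) -> np.ndarray:
    """Instantaneous measured-signal curve ``C_meas`` at the requested times."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValidationError("model times must be >= 0")
    knots = _support_grid(aif, times, float(times.max()))
    res = resample_input(aif, knots, hold_last=hold_last)
    y = _pwl_exp_response(knots, res.cp, params.k2)
    ct = params.k1 * y
    if va_formulation == VA_STANDARD:
        cmeas = (1.0 - params.va) * ct + params.va * res.cb
    elif va_formulation == VA_ADDITIVE:
        cmeas = ct + params.va * res.cb
    else:
        raise ValidationError(f"unknown Va formulation {va_formulation!r}")
    idx = np.searchsorted(knots, times)
    return cmeas[idx]


def predict_frames(
    params: KineticParams,
    aif: InputFunction,
    schedule: FrameSchedule,
    va_formulation: str = VA_STANDARD,
    hold_last: bool = False,
) -> TimeActivityCurve:
    """Frame-averaged model prediction on an acquisition schedule.

    Each frame value is the exact time-average of ``C_meas`` over the frame
    interval.  If the schedule extends beyond the AIF support an error is
    raised unless ``hold_last`` is set.
    """
    pred = _FramePredictor(aif, schedule, hold_last=hold_last)
    values = pred.frame_means(params.k1, params.k2, params.va, va_formulation)
    return TimeActivityCurve(
        values, schedule=schedule, decay_corrected=True, decay_reference_min=0.0
    )


@dataclass(frozen=True)
class KineticFit:
    """Result of a one-tissue-compartment fit.

    ``vt`` always equals ``params.k1 / params.k2``.  ``residuals`` are
    observed minus fitted frame values (unweighted); ``weights`` is the
    weight vector the objective used.  A non-converged fit is returned as a
    flagged failure (``converged=False``) rather than raising, matching how
    occasional unfittable VOIs are reported rather than dropped.
    """

    params: KineticParams
    vt: float
    wrss: float
    residuals: np.ndarray
    fitted: np.ndarray
    observed: np.ndarray
    weights: np.ndarray
    schedule: FrameSchedule
    converged: bool
    n_starts: int
    message: str = ""
    aif_source: str = ""
    va_formulation: str = VA_STANDARD
    hold_last: bool = False

    def to_dict(self) -> dict:
        return {
            "K1": self.params.k1,
            "k2": self.params.k2,
            "Va": self.params.va,
            "VT": self.vt,
            "wrss": self.wrss,
            "residuals": self.residuals.tolist(),
            "fitted": self.fitted.tolist(),
            "converged": self.converged,
            "n_starts": self.n_starts,
            "message": self.message,
            "aif_source": self.aif_source,
            "va_formulation": self.va_formulation,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _resolve_weights(weights, schedule: FrameSchedule) -> np.ndarray:
    if isinstance(weights, str):
        if weights == "duration":
            return schedule.duration_min.copy()
        if weights == "uniform":
            return np.ones(schedule.n_frames)
        raise ValidationError(f"unknown weighting scheme {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,) or np.any(w <= 0):
        raise ValidationError("weight vector must be positive, one per frame")
    return w


def fit_1tcm(
    tac: TimeActivityCurve,
    aif: InputFunction,
    weights="duration",
    init: KineticParams | None = None,
    bounds=DEFAULT_BOUNDS,
    va_formulation: str = VA_STANDARD,
    hold_last: bool = False,
) -> KineticFit:
    """Bounded weighted least-squares fit of (K1, k2, Va) to a framed TAC.

    Minimises ``sum_i w_i (tac_i - pred_i)^2`` with ``w_i`` proportional to
    frame duration by default (longer frames integrate more counts).  Unless
    an explicit ``init`` is given, a deterministic multi-start grid is used
    and the best weighted residual sum of squares wins; exact ties break to
    the lowest K1, then lowest k2.  Both acquisition phases of a two-phase
    schedule are fitted jointly (they share one schedule).
    """
    if not tac.is_framed:
        raise FitError("fitting requires a framed TAC (frame schedule with durations)")
    schedule = tac.schedule
    if schedule.n_frames < 4:
        raise FitError("need >= 4 frames to fit 3 parameters")
    w = _resolve_weights(weights, schedule)
    sw = np.sqrt(w)
    obs = tac.values
    predictor = _FramePredictor(aif, schedule, hold_last=hold_last)
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    # a parameter may be pinned by equal bounds; widen infinitesimally for
    # the optimizer, which requires lb < ub strictly
    hi = np.where(hi - lo < 1e-10, lo + 1e-10, hi)
    k2_floor = max(lo[1], 1e-6)

    def residual(x):
        pred = predictor.frame_means(x[0], max(x[1], k2_floor), x[2], va_formulation)
        return sw * (obs - pred)

    if init is not None:
        starts = [init.as_array()]
    else:
        starts = [np.array(s) for s in DEFAULT_START_GRID]
    starts = [np.clip(s, lo + 1e-12, hi - 1e-12) for s in starts]

    best = None
    best_wrss = np.inf
    any_ok = False
    message = ""
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # pragma: no cover - scipy failures are rare
            message = str(exc)
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            message = sol.message
            continue
        any_ok = True
        wrss = float(2.0 * sol.cost)
        tie = abs(wrss - best_wrss) <= 1e-10 * max(1.0, best_wrss)
        better = wrss < best_wrss - 1e-10 * max(1.0, best_wrss)
        if best is None or better or (
            tie and (sol.x[0], sol.x[1]) < (best.x[0], best.x[1])
        ):
            best, best_wrss = sol, wrss

    if not any_ok:
        nan = float("nan")
        return KineticFit(
            params=KineticParams(0.0, k2_floor, 0.0),
            vt=nan,
            wrss=nan,
            residuals=np.full(schedule.n_frames, nan),
            fitted=np.full(schedule.n_frames, nan),
            observed=obs.copy(),
            weights=w,
            schedule=schedule,
            converged=False,
            n_starts=len(starts),
            message=message or "no start converged",
            aif_source=aif.source,
            va_formulation=va_formulation,
            hold_last=hold_last,
        )

    k1, k2, va = best.x
    k2 = max(k2, k2_floor)
    params = KineticParams(float(k1), float(k2), float(min(max(va, 0.0), 1.0)))
    fitted = predictor.frame_means(params.k1, params.k2, params.va, va_formulation)
    return KineticFit(
        params=params,
        vt=compute_vt(params),
        wrss=best_wrss,
        residuals=obs - fitted,
        fitted=fitted,
        observed=obs.copy(),
        weights=w,
        schedule=schedule,
        converged=True,
        n_starts=len(starts),
        message="converged",
        aif_source=aif.source,
        va_formulation=va_formulation,
        hold_last=hold_last,
    )
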
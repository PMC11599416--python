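"""Synthetic study generator: every pipeline input, with ground truth.

Emulates the rat cell-sheet tracking study at desk scale: a bolus-shaped
arterial curve peaking within a few minutes of injection, a two-phase
16-frame / 180-min acquisition, a high-retention transplanted-sheet region
(VT around 1.35), a washout myocardium (VT around 0.3), a blood-volume
fraction of 0.29 ml/ml, count-statistics-like noise, and the 6-session
longitudinal design (days 1, 4, 7, 10, 15, 23).  All generators are
seed-deterministic and return their ground truth alongside the data so
every downstream stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .input_function import DEFAULT_PLASMA_RATIO, InputFunction, SOURCE_LV
from .kinetics import KineticParams, predict_frames
from .tac_core import (
    DoseRecord,
    DynamicImage,
    FrameSchedule,
    TimeActivityCurve,
    VOIMask,
    build_frame_schedule,
)

# ---------------------------------------------------------------------------
# Kinetic presets anchored to the study's reported magnitudes.
# ---------------------------------------------------------------------------

#: Transplanted reporter-expressing cell sheet: high retention.
SHEET_PARAMS = KineticParams(k1=0.095, k2=0.095 / 1.35, va=0.29)
#: Normal myocardium: prompt washout, low retention.
MYOCARDIUM_PARAMS = KineticParams(k1=0.07, k2=0.07 / 0.30, va=0.29)
#: Non-specific uptake (e.g. injured lung): much higher K1 and VT than sheet.
LUNG_NONSPECIFIC_PARAMS = KineticParams(k1=0.5, k2=0.5 / 2.0, va=0.29)

PRESETS = {
    "sheet": SHEET_PARAMS,
    "myocardium": MYOCARDIUM_PARAMS,
    "lung_nonspecific": LUNG_NONSPECIFIC_PARAMS,
}

#: The study's two-phase dynamic protocol: 8 x 2.5 min then 8 x 20 min.
DEFAULT_PHASES = ((8, 2.5), (8, 20.0))


def default_schedule() -> FrameSchedule:
    return build_frame_schedule(DEFAULT_PHASES)


# ---------------------------------------------------------------------------
# Arterial input model.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AifModelParams:
    """Bolus input model: linear rise from 0 over [0, t_peak], then a
    tri-exponential washout ``sum_j A_j exp(-lambda_j (t - t_peak))``.

    Amplitudes are kBq/ml (whole blood) and sum to the peak value, rates are
    1/min.  Defaults give a sharp peak 1 min after injection, washout to
    about a fifth of the peak by 20 min, and a slowly declining tail over
    the 3-h experiment (pertechnetate equilibrates with extracellular fluid
    and is excreted slowly, so whole-blood activity does not fall to zero).
    Under the sheet kinetic preset this input reproduces the reported tissue
    curve shape: frame activity peaking 40-60 min after injection.
    """

    amplitudes: tuple = (2800.0, 600.0, 900.0)
    rates: tuple = (3.0, 0.15, 0.001)
    t_peak_min: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.amplitudes, dtype=float)
        lam = np.asarray(self.rates, dtype=float)
        if a.size != lam.size or a.size == 0:
            raise ValidationError("amplitudes and rates must be equal-length, non-empty")
        if not (self.t_peak_min > 0):
            raise ValidationError("t_peak must be > 0")
        if np.any(lam < 0):
            raise ValidationError("decay rates must be >= 0")
        # Negative amplitudes are allowed in multi-exponential shaping only
        # while the summed curve stays non-negative; checked on a fine grid.
        t = np.linspace(0.0, 240.0, 2001)
        if np.any(self._raw(t) < -1e-12):
            raise ValidationError("AIF model yields negative concentrations")

    def _raw(self, t: np.ndarray) -> np.ndarray:
        a = np.asarray(self.amplitudes, dtype=float)
        lam = np.asarray(self.rates, dtype=float)
        peak = float(a.sum())
        rise = peak * np.clip(t / self.t_peak_min, 0.0, 1.0)
        dt = np.maximum(t - self.t_peak_min, 0.0)
        decay = np.sum(a[:, None] * np.exp(-lam[:, None] * dt[None, :]), axis=0)
        return np.where(t <= self.t_peak_min, rise, decay)

    def evaluate(self, times):
        """Whole-blood concentration Cb(t) (kBq/ml); Cb(0) = 0."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.maximum(self._raw(t), 0.0)
        return out[0] if np.ndim(times) == 0 else out


DEFAULT_AIF_MODEL = AifModelParams()


def simulate_aif(
    model: AifModelParams = DEFAULT_AIF_MODEL,
    times=None,
    plasma_ratio: float = DEFAULT_PLASMA_RATIO,
    source: str = SOURCE_LV,
) -> InputFunction:
    """Sample the bolus model onto a time grid and derive plasma = ratio x blood.

    The default grid is dense (0.1 min) over the first phase and coarser
    afterwards, spanning the 180-min protocol.
    """
    if times is None:
        times = np.unique(np.concatenate([np.arange(0.0, 20.0, 0.1), np.arange(20.0, 180.01, 0.5)]))
    t = np.asarray(times, dtype=float)
    cb = model.evaluate(t)
    return InputFunction(
        times_min=t, cb=cb, cp=plasma_ratio * cb, source=source, plasma_ratio=plasma_ratio
    )


def simulate_tissue_tac(
    params: KineticParams, aif: InputFunction, schedule: FrameSchedule, **kwargs
) -> TimeActivityCurve:
    """Noiseless frame-averaged tissue TAC for the given kinetics (forward model)."""
    return predict_frames(params, aif, schedule, **kwargs)


def add_noise(
    tac: TimeActivityCurve,
    seed: int,
    model: str = "scaled_poisson",
    alpha: float = 1.0,
    fraction: float = 0.05,
) -> TimeActivityCurve:
    """Add frame noise to a noiseless TAC; deterministic per seed.

    ``scaled_poisson`` draws Normal(mean=C_i, var=alpha*C_i/duration_i) —
    variance proportional to concentration, shrinking with frame length as
    count statistics do.  ``proportional`` draws Normal(C_i, (fraction*C_i)^2).
    Both truncate at zero (measured concentrations are non-negative).
    """
    rng = np.random.default_rng(seed)
    c = tac.values
    if model == "scaled_poisson":
        if not (alpha > 0):
            raise ValidationError("alpha must be > 0")
        if not tac.is_framed:
            raise ValidationError("scaled_poisson noise needs frame durations")
        sd = np.sqrt(alpha * np.maximum(c, 0.0) / tac.schedule.duration_min)
    elif model == "proportional":
        if not (fraction > 0):
            raise ValidationError("fraction must be > 0")
        sd = fraction * np.abs(c)
    else:
        raise ValidationError(f"unknown noise model {model!r}")
    noisy = np.maximum(c + rng.standard_normal(c.size) * sd, 0.0)
    return tac.with_values(noisy)


# ---------------------------------------------------------------------------
# Voxel phantom.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + kinetics of a small rat-heart-like digital phantom.

    Region voxel counts default to the study's mean VOI sizes (LV cavity
    406, sheet 104, myocardium 96 voxels at 0.5-mm isotropic voxels).  The
    LV region carries the whole-blood curve directly; tissue regions carry
    their one-tissue-compartment TACs.  ``noise_alpha=None`` disables noise.
    """

    shape: tuple = (40, 40, 40)
    voxel_size_mm: tuple = (0.5, 0.5, 0.5)
    region_voxels: dict = field(
        default_factory=lambda: {"LV": 406, "sheet": 104, "myocardium": 96}
    )
    region_params: dict = field(
        default_factory=lambda: {"sheet": SHEET_PARAMS, "myocardium": MYOCARDIUM_PARAMS}
    )
    noise_alpha: float | None = None
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValidationError("phantom grid must be 3-D, at least 8 voxels per axis")
        for name, n in self.region_voxels.items():
            if n < 1:
                raise ValidationError(f"region {name!r} needs >= 1 voxel")
        if sum(self.region_voxels.values()) > int(np.prod(self.shape)) // 2:
            raise ValidationError("regions would fill more than half the grid")
        for name in self.region_params:
            if name not in self.region_voxels:
                raise ValidationError(f"params given for unknown region {name!r}")


# Region anchor points (fractions of the grid), far enough apart that the
# default region sizes never collide on the default 40^3 grid.
_REGION_CENTRES = {
    "LV": (0.33, 0.5, 0.5),
    "myocardium": (0.67, 0.5, 0.5),
    "sheet": (0.5, 0.8, 0.5),
    "lung_nonspecific": (0.5, 0.2, 0.5),
}


def _region_mask(shape, centre_frac, n_voxels: int, taken: np.ndarray) -> np.ndarray:
    """Deterministic near-spherical region: the n free voxels nearest a centre."""
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centre = np.array([c * (s - 1) for c, s in zip(centre_frac, shape)])
    d2 = np.sum((idx - centre) ** 2, axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    free = ~taken.ravel()
    chosen = [i for i in order if free[i]][:n_voxels]
    if len(chosen) < n_voxels:
        raise ValidationError("grid too small for requested region sizes")
    mask[chosen] = True
    return mask.reshape(shape)


def simulate_dynamic_phantom(spec: PhantomSpec, aif: InputFunction):
    """Build a 4-D phantom image with ground-truth masks and parameters.

    Returns ``(image, masks, truth)`` where ``masks`` maps region label to
    :class:`VOIMask` and ``truth`` holds the generating kinetic parameters
    and noiseless region TACs.  Regions are disjoint by construction; each
    voxel of a region carries the region TAC (with independent per-voxel
    noise when enabled).  The image is in the decay-corrected domain.
    """
    schedule = default_schedule()
    data = np.zeros(spec.shape + (schedule.n_frames,), dtype=float)
    taken = np.zeros(spec.shape, dtype=bool)
    masks: dict = {}
    truth: dict = {"params": {}, "tacs": {}, "aif": aif, "schedule": schedule}
    rng = np.random.default_rng(spec.seed)

    region_curves: dict = {}
    for name in spec.region_voxels:
        if name == "LV":
            # blood region: whole-blood curve, frame-averaged
            curve = predict_frames(
                KineticParams(k1=0.0, k2=1.0, va=1.0), aif, schedule
            ).values
        else:
            if name not in spec.region_params:
                raise ValidationError(f"no kinetic parameters for region {name!r}")
            curve = predict_frames(spec.region_params[name], aif, schedule).values
            truth["params"][name] = spec.region_params[name]
        region_curves[name] = curve

    for name, n_vox in spec.region_voxels.items():
        centre = _REGION_CENTRES.get(name, (0.5, 0.5, 0.5))
        m = _region_mask(spec.shape, centre, n_vox, taken)
        if (m & taken).any():
            raise ValidationError(f"region {name!r} overlaps a previous region")
        taken |= m
        masks[name] = VOIMask(m, label=name if name in ("LV", "sheet", "myocardium") else "other")
        curve = region_curves[name]
        truth["tacs"][name] = TimeActivityCurve(
            curve, schedule=schedule, decay_corrected=True, decay_reference_min=0.0
        )
        vox_idx = np.argwhere(m)
        if spec.noise_alpha is None:
            data[m] = curve
        else:
            sd = np.sqrt(spec.noise_alpha * np.maximum(curve, 0.0) / schedule.duration_min)
            for (i, j, k) in vox_idx:
                data[i, j, k] = np.maximum(
                    curve + rng.standard_normal(curve.size) * sd, 0.0
                )
    image = DynamicImage(data, spec.voxel_size_mm, schedule, decay_corrected=True)
    return image, masks, truth


# ---------------------------------------------------------------------------
# Longitudinal series.
# ---------------------------------------------------------------------------

#: Injected doses (MBq) and body weights (g) of the serially imaged subject.
DEFAULT_SESSION_DOSES = (662.0, 454.4, 508.0, 469.0, 384.2, 476.5)
DEFAULT_SESSION_WEIGHTS = (182.0, 180.0, 182.0, 185.0, 195.0, 216.0)
DEFAULT_SESSION_DAYS = (1, 4, 7, 10, 15, 23)

# Sheet-region trajectory emulating the study's course: K1 drifts up until
# day 15 then holds; VT declines steadily and plateaus above the myocardium
# preset; Va stays at the study mean 0.29.
_DEFAULT_K1 = (0.070, 0.075, 0.080, 0.086, 0.090, 0.090)
_DEFAULT_VT = (1.35, 1.05, 0.80, 0.62, 0.50, 0.49)


def _default_trajectory():
    return tuple(
        KineticParams(k1=k1, k2=k1 / vt, va=0.29) for k1, vt in zip(_DEFAULT_K1, _DEFAULT_VT)
    )


@dataclass(frozen=True)
class LongitudinalSpec:
    """Multi-session design: per-day sheet kinetics, shared AIF model, doses."""

    days: tuple = DEFAULT_SESSION_DAYS
    sheet_trajectory: tuple = field(default_factory=_default_trajectory)
    myocardium_params: KineticParams = MYOCARDIUM_PARAMS
    aif_model: AifModelParams = DEFAULT_AIF_MODEL
    doses_mbq: tuple = DEFAULT_SESSION_DOSES
    body_weights_g: tuple = DEFAULT_SESSION_WEIGHTS
    plasma_ratio: float = DEFAULT_PLASMA_RATIO
    noise_alpha: float | None = None
    require_nonincreasing_vt: bool = True

    def __post_init__(self):
        n = len(self.days)
        if n < 2:
            raise ValidationError("a longitudinal design needs >= 2 sessions")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValidationError("session days must be strictly increasing")
        if not (len(self.sheet_trajectory) == len(self.doses_mbq) == len(self.body_weights_g) == n):
            raise ValidationError("trajectory, doses and weights must match the number of days")
        if self.require_nonincreasing_vt:
            vts = [p.vt for p in self.sheet_trajectory]
            if any(b > a + 1e-12 for a, b in zip(vts, vts[1:])):
                raise ValidationError("sheet VT trajectory must be non-increasing")


@dataclass(frozen=True)
class SyntheticSession:
    """One simulated imaging day with its ground truth."""

    day: int
    aif: InputFunction
    sheet_tac: TimeActivityCurve
    myocardium_tac: TimeActivityCurve
    dose: DoseRecord
    sheet_params: KineticParams
    myocardium_params: KineticParams


def simulate_longitudinal_series(spec: LongitudinalSpec, seed: int = 0) -> list:
    """Simulate the per-day TAC data of a serial tracking study.

    Each session shares the AIF model and schedule; the sheet region follows
    the specified kinetic trajectory.  Noise (if enabled) is independent
    across sessions but fully determined by ``seed``.
    """
    schedule = default_schedule()
    aif = simulate_aif(spec.aif_model, plasma_ratio=spec.plasma_ratio)
    sessions = []
    for i, day in enumerate(spec.days):
        sheet = simulate_tissue_tac(spec.sheet_trajectory[i], aif, schedule)
        myo = simulate_tissue_tac(spec.myocardium_params, aif, schedule)
        if spec.noise_alpha is not None:
            sheet = add_noise(sheet, seed=seed * 1009 + 2 * i, alpha=spec.noise_alpha)
            myo = add_noise(myo, seed=seed * 1009 + 2 * i + 1, alpha=spec.noise_alpha)
        sessions.append(
            SyntheticSession(
                day=int(day),
                aif=aif,
                sheet_tac=sheet,
                myocardium_tac=myo,
                dose=DoseRecord(spec.doses_mbq[i], spec.body_weights_g[i]),
                sheet_params=spec.sheet_trajectory[i],
                myocardium_params=spec.myocardium_params,
            )
        )
    return sessions


def avs_counts_from_aif(aif: InputFunction, cross_calibration: float = 1.0) -> np.ndarray:
    """Detector-counts table (time_min, counts) consistent with an AIF.

    The returned counts divided by ``cross_calibration`` reproduce the AIF's
    whole-blood curve, mimicking a cross-calibrated shunt detector.
    """
    if not (cross_calibration > 0):
        raise ValidationError("cross-calibration factor must be > 0")
    return np.column_stack([aif.times_min, aif.cb / cross_calibration])
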
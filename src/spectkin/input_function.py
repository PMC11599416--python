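"""Arterial input function construction.

Two routes to the plasma input driving the tissue model:

* **LV_IMAGE** — the whole-blood curve is the mean of a VOI drawn on the
  left-ventricular cavity of the (decay-corrected) dynamic image;
* **AVS** — continuous counts from a detector on the arterial limb of an
  arteriovenous shunt, cross-calibrated to kBq/ml.

Either way the plasma concentration is obtained by scaling whole blood with
a single time-invariant plasma-to-whole-blood ratio (measured to be nearly
constant over the 3-h pertechnetate experiment; study mean 1.239).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tac_core import DynamicImage, VOIMask, extract_tac

#: Study-mean plasma-to-whole-blood activity ratio for pertechnetate in rat.
DEFAULT_PLASMA_RATIO = 1.239

SOURCE_LV = "LV_IMAGE"
SOURCE_AVS = "AVS"
_SOURCES = (SOURCE_LV, SOURCE_AVS)


@dataclass(frozen=True)
class PlasmaRatio:
    """Scalar plasma/whole-blood activity ratio, optionally with the
    per-sample measurements it was averaged from."""

    ratio: float = DEFAULT_PLASMA_RATIO
    measurements: pd.DataFrame | None = None

    def __post_init__(self):
        if not (self.ratio > 0):
            raise ValidationError("plasma ratio must be > 0")


def estimate_plasma_ratio(samples) -> PlasmaRatio:
    """Average per-sample plasma/whole-blood ratios from discrete draws.

    ``samples`` is a DataFrame (or array) with columns
    ``(time_min, plasma_kBq_ml, wholeblood_kBq_ml)``.  The protocol draws at
    2.5, 5, 10, 20, 40, 60, 120 and 180 min, but any grid is accepted.
    """
    if isinstance(samples, pd.DataFrame):
        arr = samples.to_numpy(dtype=float)
    else:
        arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
        raise ValidationError("expected >= 1 sample rows of (time, plasma, whole_blood)")
    plasma, whole = arr[:, 1], arr[:, 2]
    if np.any(whole <= 0):
        raise ValidationError("whole-blood activity must be > 0 in every sample")
    if np.any(plasma <= 0):
        raise ValidationError("plasma activity must be > 0 in every sample")
    df = pd.DataFrame(arr, columns=["time_min", "plasma_kBq_ml", "wholeblood_kBq_ml"])
    return PlasmaRatio(ratio=float(np.mean(plasma / whole)), measurements=df)


@dataclass(frozen=True)
class InputFunction:
    """Whole-blood and plasma concentration curves with provenance.

    ``cp = plasma_ratio * cb`` pointwise when derived by the scalar ratio.
    Times are minutes since injection, strictly increasing.
    """

    times_min: np.ndarray
    cb: np.ndarray
    cp: np.ndarray
    source: str
    plasma_ratio: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        cb = np.asarray(self.cb, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("input function needs >= 2 time samples")
        if cb.shape != t.shape or cp.shape != t.shape:
            raise ValidationError("cb/cp must match the time grid")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("input-function times must be strictly increasing")
        if not (np.all(np.isfinite(cb)) and np.all(np.isfinite(cp))):
            raise ValidationError("input-function values must be finite")
        if np.any(cb < 0) or np.any(cp < 0):
            raise ValidationError("input-function concentrations must be >= 0")
        if self.source not in _SOURCES:
            raise ValidationError(f"source must be one of {_SOURCES}, got {self.source!r}")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "cb", cb)
        object.__setattr__(self, "cp", cp)

    def with_source(self, source: str) -> "InputFunction":
        return dataclasses.replace(self, source=source)


def aif_from_lv(
    image: DynamicImage, lv_mask: VOIMask, ratio: PlasmaRatio | float = DEFAULT_PLASMA_RATIO
) -> InputFunction:
    """Image-derived input function from a left-ventricular cavity VOI."""
    if lv_mask.label != "LV":
        raise ValidationError(f"expected a mask labelled 'LV', got {lv_mask.label!r}")
    r = ratio.ratio if isinstance(ratio, PlasmaRatio) else float(ratio)
    tac = extract_tac(image, lv_mask)
    cb = tac.values
    return InputFunction(
        times_min=tac.times_min, cb=cb, cp=r * cb, source=SOURCE_LV, plasma_ratio=r
    )


def aif_from_avs(
    counts_table,
    cross_calibration: float,
    ratio: PlasmaRatio | float = DEFAULT_PLASMA_RATIO,
) -> InputFunction:
    """Input function from arteriovenous-shunt detector counts.

    ``counts_table`` holds ``(time_min, counts)`` rows (DataFrame or array);
    ``cross_calibration`` converts detector counts to kBq/ml (from a
    cross-calibration against the SPECT scanner / well counter).
    """
    if not (cross_calibration > 0):
        raise ValidationError("cross-calibration factor must be > 0")
    if isinstance(counts_table, pd.DataFrame):
        arr = counts_table.to_numpy(dtype=float)
    else:
        arr = np.asarray(counts_table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("expected (time_min, counts) rows")
    t, counts = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValidationError("AVS times must be strictly increasing")
    r = ratio.ratio if isinstance(ratio, PlasmaRatio) else float(ratio)
    cb = cross_calibration * counts
    return InputFunction(times_min=t, cb=cb, cp=r * cb, source=SOURCE_AVS, plasma_ratio=r)


def resample_input(aif: InputFunction, grid, hold_last: bool = False) -> InputFunction:
    """Linearly resample an input function onto a new time grid.

    Before the first sample the curve is taken as 0 (pre-injection); beyond
    the last sample the last value is held only if ``hold_last`` is set,
    otherwise extrapolation is an error.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValidationError("resampling grid must not be empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValidationError("resampling grid must be strictly increasing")
    t = aif.times_min
    if grid[-1] > t[-1] + 1e-9 and not hold_last:
        raise ValidationError(
            f"grid extends to {grid[-1]:g} min beyond AIF support ({t[-1]:g} min); "
            "pass hold_last=True to hold the final value"
        )
    cb = np.interp(grid, t, aif.cb, left=0.0, right=aif.cb[-1])
    cp = np.interp(grid, t, aif.cp, left=0.0, right=aif.cp[-1])
    if grid.size < 2:
        # The InputFunction type needs >= 2 samples; duplicate-grid queries
        # should use np.interp directly — keep the contract strict here.
        raise ValidationError("resampling grid needs >= 2 points to form an InputFunction")
    return InputFunction(
        times_min=grid, cb=cb, cp=cp, source=aif.source, plasma_ratio=aif.plasma_ratio
    )
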
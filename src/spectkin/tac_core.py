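"""Core data types and corrections for dynamic SPECT time-activity data.

Conventions used throughout the package:

* time is measured in minutes since tracer injection (injection = t = 0);
* activity concentration is kBq/ml;
* model and correction evaluations for a frame use the frame *mid-time*,
  because late frames are long (up to 20 min) and the start-time convention
  would bias decay factors and model predictions;
* volumes-of-interest are binary voxel masks on the image grid (no
  resampling, no partial-volume weighting).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ParseError, UnitsError, ValidationError

#: Physical half-life of 99mTc in hours.
TC99M_HALF_LIFE_HOURS = 6.0058

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition timing of a dynamic scan.

    Parameters
    ----------
    start_min:
        Frame start times in minutes since injection, strictly increasing.
    duration_min:
        Frame durations in minutes, all positive.  Frames must not overlap
        (``start[i+1] >= start[i] + duration[i]``) but gaps are allowed.
    """

    start_min: np.ndarray
    duration_min: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_min, dtype=float)
        dur = np.asarray(self.duration_min, dtype=float)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise ValidationError("start_min and duration_min must be 1-D and equal length")
        if start.size == 0:
            raise ValidationError("schedule needs at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise ValidationError("frame times must be finite")
        if np.any(dur <= 0):
            raise ValidationError("all frame durations must be > 0")
        if start.size > 1 and np.any(np.diff(start) <= 0):
            raise ValidationError("frame starts must be strictly increasing")
        if np.any(start[1:] + _TIME_TOL < start[:-1] + dur[:-1]):
            raise ValidationError("frames must not overlap")
        object.__setattr__(self, "start_min", start)
        object.__setattr__(self, "duration_min", dur)

    @property
    def n_frames(self) -> int:
        return self.start_min.size

    @property
    def end_min(self) -> np.ndarray:
        return self.start_min + self.duration_min

    @property
    def mid_min(self) -> np.ndarray:
        """Frame mid-times, the package's timestamp convention."""
        return self.start_min + 0.5 * self.duration_min

    @property
    def total_duration_min(self) -> float:
        return float(self.end_min[-1] - self.start_min[0])


def build_frame_schedule(phase_specs) -> FrameSchedule:
    """Build a contiguous multi-phase schedule starting at injection.

    ``phase_specs`` is a sequence of ``(n_frames, frame_minutes)`` pairs; e.g.
    ``[(8, 2.5), (8, 20.0)]`` yields the 16-frame, 180-min two-phase protocol
    (eight 2.5-min frames followed by eight 20-min frames).
    """
    starts, durs = [], []
    t = 0.0
    for n, d in phase_specs:
        if int(n) != n or n < 1:
            raise ValidationError(f"phase frame count must be a positive integer, got {n!r}")
        if not (d > 0):
            raise ValidationError(f"phase frame duration must be > 0, got {d!r}")
        for _ in range(int(n)):
            starts.append(t)
            durs.append(float(d))
            t += float(d)
    if not starts:
        raise ValidationError("at least one phase is required")
    return FrameSchedule(np.array(starts), np.array(durs))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration versus time for a VOI or blood pool.

    Exactly one of ``schedule`` (framed dynamic data) or ``sample_times_min``
    (discrete blood draws) must be provided.  ``values`` carries one number
    per frame/sample.  Values must be finite; negativity is tolerated at the
    type level because model residual arithmetic (e.g. bootstrap replicate
    curves) can dip below zero — physical readers enforce non-negativity.
    """

    values: np.ndarray
    schedule: FrameSchedule | None = None
    sample_times_min: np.ndarray | None = None
    units: str = "kBq/ml"
    decay_corrected: bool = False
    decay_reference_min: float | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValidationError("values must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ValidationError("values must be finite")
        if (self.schedule is None) == (self.sample_times_min is None):
            raise ValidationError("provide exactly one of schedule or sample_times_min")
        if self.schedule is not None:
            if values.size != self.schedule.n_frames:
                raise ValidationError("one value per frame required")
        else:
            t = np.asarray(self.sample_times_min, dtype=float)
            if t.ndim != 1 or t.size != values.size:
                raise ValidationError("one value per sample time required")
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValidationError("sample times must be strictly increasing")
            object.__setattr__(self, "sample_times_min", t)
        object.__setattr__(self, "values", values)

    @property
    def is_framed(self) -> bool:
        return self.schedule is not None

    @property
    def times_min(self) -> np.ndarray:
        """Representative times: frame mid-times or discrete sample times."""
        if self.schedule is not None:
            return self.schedule.mid_min
        return self.sample_times_min

    def with_values(self, values, **changes) -> "TimeActivityCurve":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass(frozen=True)
class DynamicImage:
    """A 4-D dynamic volume (x, y, z, frame) in calibrated kBq/ml."""

    data: np.ndarray
    voxel_size_mm: tuple
    schedule: FrameSchedule
    decay_corrected: bool = False

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValidationError("dynamic image data must be 4-D (x, y, z, frame)")
        if data.shape[3] != self.schedule.n_frames:
            raise ValidationError(
                f"frame axis ({data.shape[3]}) does not match schedule ({self.schedule.n_frames})"
            )
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValidationError("voxel_size_mm must be three positive edge lengths")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", vox)

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass(frozen=True)
class VOIMask:
    """Binary volume-of-interest mask aligned to a DynamicImage grid."""

    mask: np.ndarray
    label: str = "other"

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask.astype(bool)
        if mask.ndim != 3:
            raise ValidationError("VOI mask must be 3-D")
        if not mask.any():
            raise ValidationError("VOI mask must select at least one voxel")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class DoseRecord:
    """Injected dose and subject weight for SUV bookkeeping."""

    dose_mbq: float
    body_weight_g: float
    injection_time: str | None = None

    def __post_init__(self):
        if not (self.dose_mbq > 0):
            raise ValidationError("injected dose must be > 0")
        if not (self.body_weight_g > 0):
            raise ValidationError("body weight must be > 0")


def extract_tac(image: DynamicImage, mask: VOIMask) -> TimeActivityCurve:
    """Mean activity concentration over the mask, per frame.

    The VOI mean is the unweighted mean over the included voxels (binary
    mask); the schedule is copied from the image.
    """
    if mask.mask.shape != image.spatial_shape:
        raise ValidationError(
            f"mask shape {mask.mask.shape} does not match image grid {image.spatial_shape}"
        )
    values = image.data[mask.mask].mean(axis=0)
    return TimeActivityCurve(
        values=values,
        schedule=image.schedule,
        decay_corrected=image.decay_corrected,
        decay_reference_min=0.0 if image.decay_corrected else None,
    )


def decay_correct(
    tac: TimeActivityCurve,
    half_life_hours: float = TC99M_HALF_LIFE_HOURS,
    reference_min: float = 0.0,
) -> TimeActivityCurve:
    """Correct physical decay back to a reference time (default: injection).

    Each value is multiplied by ``2**((t - reference) / T_half)`` with ``t``
    the frame mid-time (or sample time).  Correcting an already-corrected
    curve raises, to guard against silent double correction.
    """
    if not (half_life_hours > 0):
        raise ValidationError("half-life must be > 0")
    if tac.decay_corrected:
        raise ValidationError("curve is already decay-corrected")
    half_life_min = half_life_hours * 60.0
    factors = 2.0 ** ((tac.times_min - reference_min) / half_life_min)
    return tac.with_values(
        tac.values * factors, decay_corrected=True, decay_reference_min=reference_min
    )


def decay_uncorrect(
    tac: TimeActivityCurve, half_life_hours: float = TC99M_HALF_LIFE_HOURS
) -> TimeActivityCurve:
    """Invert :func:`decay_correct`, restoring the measured (decaying) curve."""
    if not tac.decay_corrected:
        raise ValidationError("curve is not decay-corrected")
    half_life_min = half_life_hours * 60.0
    ref = tac.decay_reference_min if tac.decay_reference_min is not None else 0.0
    factors = 2.0 ** (-(tac.times_min - ref) / half_life_min)
    return tac.with_values(
        tac.values * factors, decay_corrected=False, decay_reference_min=None
    )


def compute_suv(tac: TimeActivityCurve, dose: DoseRecord) -> TimeActivityCurve:
    """Standardised uptake value: concentration / (injected dose / body weight).

    With concentration in kBq/ml, dose in MBq and weight in grams (tissue
    density taken as 1 g/ml) the result is dimensionless.
    """
    if tac.units != "kBq/ml":
        raise UnitsError(f"SUV scaling expects kBq/ml input, got units {tac.units!r}")
    suv = tac.values * dose.body_weight_g / (dose.dose_mbq * 1e3)
    return tac.with_values(suv, units="SUV")


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Dialect: comma-separated, "." decimal, mandatory
# header; an optional leading "#"-comment carries units / correction flags so
# round-trips are lossless.
# ---------------------------------------------------------------------------

_FRAMED_COLS = ["time_start_min", "duration_min", "value_kBq_per_ml"]
_DISCRETE_COLS = ["time_min", "value"]


def write_tac_table(tac: TimeActivityCurve, path) -> None:
    """Write a TAC as CSV (framed or discrete layout, chosen by the curve)."""
    path = Path(path)
    meta = (
        f"# units={tac.units};decay_corrected={str(tac.decay_corrected).lower()};"
        f"reference_min={'' if tac.decay_reference_min is None else repr(tac.decay_reference_min)}"
    )
    if tac.is_framed:
        df = pd.DataFrame(
            {
                _FRAMED_COLS[0]: tac.schedule.start_min,
                _FRAMED_COLS[1]: tac.schedule.duration_min,
                _FRAMED_COLS[2]: tac.values,
            }
        )
    else:
        df = pd.DataFrame({_DISCRETE_COLS[0]: tac.sample_times_min, _DISCRETE_COLS[1]: tac.values})
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _parse_meta(line: str) -> dict:
    out = {}
    for item in line.lstrip("#").strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_tac_table(path) -> TimeActivityCurve:
    """Read a TAC CSV written by :func:`write_tac_table` (or hand-made).

    Accepts the framed layout ``time_start_min,duration_min,value_kBq_per_ml``
    or the discrete layout ``time_min,value``.  Parse and validation failures
    name the offending 1-based file line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta: dict = {}
    first_data_line = 1
    idx = 0
    if lines and lines[0].startswith("#"):
        meta = _parse_meta(lines[0])
        idx = 1
    if idx >= len(lines) or not lines[idx].strip():
        raise ParseError("missing header row", path=path, line=idx + 1)
    header = [c.strip() for c in lines[idx].split(",")]
    first_data_line = idx + 2
    if header == _FRAMED_COLS:
        framed = True
    elif header == _DISCRETE_COLS:
        framed = False
    else:
        raise ParseError(
            f"unrecognised header {header!r}; expected {_FRAMED_COLS} or {_DISCRETE_COLS}",
            path=path,
            line=idx + 1,
        )
    rows = []
    for i, raw in enumerate(lines[idx + 1 :]):
        if not raw.strip():
            continue
        cells = [c.strip() for c in raw.split(",")]
        if len(cells) != len(header):
            raise ParseError(
                f"expected {len(header)} columns, found {len(cells)}",
                path=path,
                line=first_data_line + i,
            )
        try:
            vals = [float(c) for c in cells]
        except ValueError:
            raise ParseError(f"non-numeric cell in row {cells!r}", path=path, line=first_data_line + i)
        if framed and vals[1] <= 0:
            raise ParseError(f"non-positive frame duration {vals[1]}", path=path, line=first_data_line + i)
        if vals[-1] < 0:
            raise ParseError(f"negative activity value {vals[-1]}", path=path, line=first_data_line + i)
        rows.append(vals)
    if not rows:
        raise ParseError("no data rows", path=path, line=first_data_line)
    arr = np.asarray(rows, dtype=float)
    units = meta.get("units", "kBq/ml")
    corrected = meta.get("decay_corrected", "false") == "true"
    ref_raw = meta.get("reference_min", "")
    ref = float(ref_raw) if ref_raw else (0.0 if corrected else None)
    try:
        if framed:
            schedule = FrameSchedule(arr[:, 0], arr[:, 1])
            return TimeActivityCurve(
                arr[:, 2], schedule=schedule, units=units,
                decay_corrected=corrected, decay_reference_min=ref,
            )
        return TimeActivityCurve(
            arr[:, 1], sample_times_min=arr[:, 0], units=units,
            decay_corrected=corrected, decay_reference_min=ref,
        )
    except ValidationError as exc:
        raise ParseError(str(exc), path=path) from exc


# ---------------------------------------------------------------------------
# NIfTI-1 volume I/O with a JSON sidecar carrying the frame schedule.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_dynamic_image(image: DynamicImage, path) -> None:
    """Write a 4-D NIfTI-1 volume plus a timing sidecar JSON next to it."""
    path = Path(path)
    affine = np.diag(list(image.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(path))
    sidecar = {
        "frame_start_min": image.schedule.start_min.tolist(),
        "frame_duration_min": image.schedule.duration_min.tolist(),
        "injection_time": "t=0",
        "decay_corrected": image.decay_corrected,
        "units": "kBq/ml",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_dynamic_image(path) -> DynamicImage:
    """Load a 4-D NIfTI-1 volume and its timing sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D volume, got shape {data.shape}")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ValidationError(f"missing frame-schedule sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    schedule = FrameSchedule(
        np.asarray(sidecar["frame_start_min"], dtype=float),
        np.asarray(sidecar["frame_duration_min"], dtype=float),
    )
    voxel = tuple(np.abs(np.diag(img.affine)[:3]))
    return DynamicImage(
        data, voxel, schedule, decay_corrected=bool(sidecar.get("decay_corrected", False))
    )


def save_voi_mask(mask: VOIMask, path, voxel_size_mm=(0.5, 0.5, 0.5)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(Path(path)))


def load_voi_mask(path, label: str = "other") -> VOIMask:
    img = nib.load(str(Path(path)))
    return VOIMask(np.asarray(img.dataobj) > 0, label=label)
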
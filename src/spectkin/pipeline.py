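"""Configuration-driven orchestration of single-session and longitudinal runs.

A session runs: load (or synthesise) the dynamic data -> decay-correct ->
extract VOI TACs -> build the arterial input (LV image VOI and/or
arteriovenous shunt) -> plasma-correct -> fit the one-tissue model ->
bootstrap -> report.  Every number in a report is backed by a serialized
intermediate (TAC CSVs, fit JSONs, replicate CSVs) in the output directory,
and a run is byte-reproducible from its config and seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import PipelineError, ValidationError
from .input_function import (
    DEFAULT_PLASMA_RATIO,
    InputFunction,
    SOURCE_AVS,
    SOURCE_LV,
    aif_from_avs,
    aif_from_lv,
)
from .kinetics import fit_1tcm
from .synthetic_data import (
    PhantomSpec,
    avs_counts_from_aif,
    simulate_aif,
    simulate_dynamic_phantom,
    AifModelParams,
)
from .tac_core import (
    TC99M_HALF_LIFE_HOURS,
    DoseRecord,
    compute_suv,
    extract_tac,
    load_dynamic_image,
    load_voi_mask,
    write_tac_table,
)
from .uncertainty import residual_bootstrap

_TISSUE_VOIS = ("sheet", "myocardium")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run one session deterministically.

    Exactly one data source: ``synthetic`` options (phantom spec knobs) or
    ``files`` (paths to a NIfTI image + sidecar, VOI masks, optional AVS
    counts table).  ``aif_source`` is ``"LV_IMAGE"``, ``"AVS"`` or ``"both"``.
    """

    output_dir: Path
    synthetic: dict | None = None
    files: dict | None = None
    aif_source: str = SOURCE_LV
    plasma_ratio: float = DEFAULT_PLASMA_RATIO
    avs_cross_calibration: float = 1.0
    fit_options: dict = field(default_factory=dict)
    bootstrap_n: int = 200
    seed: int = 0
    session_day: int = 0
    dose_mbq: float | None = None
    body_weight_g: float | None = None
    make_plots: bool = False

    def __post_init__(self):
        if (self.synthetic is None) == (self.files is None):
            raise ValidationError("config must name exactly one data source (synthetic or files)")
        if self.aif_source not in (SOURCE_LV, SOURCE_AVS, "both"):
            raise ValidationError("aif_source must be LV_IMAGE, AVS or both")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


@dataclass
class SessionReport:
    """Per-session results: one entry per configured VOI and AIF source."""

    day: int
    fits: dict  # {voi: {source: KineticFit}}
    bootstraps: dict  # {voi: {source: BootstrapResult}}
    suv_peak: dict  # {voi: float}
    qc: dict
    output_dir: Path

    def to_dict(self) -> dict:
        return {
            "day": self.day,
            "fits": {
                voi: {src: f.to_dict() for src, f in by_src.items()}
                for voi, by_src in self.fits.items()
            },
            "bootstrap_sd": {
                voi: {src: b.sd().to_dict() for src, b in by_src.items()}
                for voi, by_src in self.bootstraps.items()
            },
            "suv_peak": self.suv_peak,
            "qc": self.qc,
        }


def _stage(name):
    """Decorator-free stage guard: wrap exceptions with the stage name."""

    class _Ctx:
        def __init__(self, n):
            self.n = n

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(self.n, str(exc)) from exc
            return False

    return _Ctx(name)


def _load_session_data(config: StudyConfig):
    """Return (image, masks, avs_table, truth-or-None) for either source."""
    if config.synthetic is not None:
        opts = dict(config.synthetic)
        aif_model = opts.pop("aif_model", AifModelParams())
        spec = PhantomSpec(seed=config.seed, **opts)
        aif_truth = simulate_aif(aif_model, plasma_ratio=config.plasma_ratio)
        image, masks, truth = simulate_dynamic_phantom(spec, aif_truth)
        # detector counts are generated at unit true calibration; the
        # configured cross-calibration is the *analysis* assumption, so a
        # miscalibrated factor propagates into the AVS input function
        avs_table = avs_counts_from_aif(aif_truth, 1.0)
        return image, masks, avs_table, truth
    files = config.files
    image_path = Path(files["image"])
    if not image_path.exists():
        raise ValidationError(f"image file not found: {image_path}")
    image = load_dynamic_image(image_path)
    masks = {}
    for label, mpath in files.get("masks", {}).items():
        mpath = Path(mpath)
        if not mpath.exists():
            raise ValidationError(f"mask file not found: {mpath}")
        masks[label] = load_voi_mask(mpath, label=label)
    avs_table = None
    if "avs_counts" in files:
        avs_path = Path(files["avs_counts"])
        if not avs_path.exists():
            raise ValidationError(f"AVS counts file not found: {avs_path}")
        avs_table = pd.read_csv(avs_path).to_numpy(dtype=float)
    return image, masks, avs_table, None


def run_session(config: StudyConfig) -> SessionReport:
    """Run the full single-session analysis; see the module docstring.

    Deterministic given the config (all randomness flows from ``seed``).
    Raises :class:`PipelineError` naming the failing stage.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "tacs").mkdir(exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)

    with _stage("load"):
        image, masks, avs_table, truth = _load_session_data(config)
        if "LV" not in masks and config.aif_source in (SOURCE_LV, "both"):
            raise ValidationError("an LV mask is required for an image-derived AIF")

    with _stage("decay_correct"):
        if not image.decay_corrected:
            # image-level correction with the frame mid-time convention
            factors = 2.0 ** (image.schedule.mid_min / (TC99M_HALF_LIFE_HOURS * 60.0))
            image = dataclasses.replace(
                image, data=image.data * factors, decay_corrected=True
            )

    with _stage("extract_tacs"):
        tacs = {label: extract_tac(image, mask) for label, mask in masks.items()}
        for label, tac in tacs.items():
            write_tac_table(tac, out / "tacs" / f"{label}.csv")

    with _stage("build_aif"):
        aifs: dict[str, InputFunction] = {}
        if config.aif_source in (SOURCE_LV, "both"):
            aifs[SOURCE_LV] = aif_from_lv(image, masks["LV"], config.plasma_ratio)
        if config.aif_source in (SOURCE_AVS, "both"):
            if avs_table is None:
                raise ValidationError("AVS counts table required for an AVS input function")
            aifs[SOURCE_AVS] = aif_from_avs(
                avs_table, config.avs_cross_calibration, config.plasma_ratio
            )

    with _stage("fit"):
        fit_opts = dict(config.fit_options)
        # An image-derived AIF is sampled at frame mid-times, so its support
        # ends half a frame before the schedule does; hold the last value.
        fit_opts.setdefault("hold_last", True)
        fits: dict = {}
        qc = {"nonconverged": []}
        for voi, tac in tacs.items():
            if voi == "LV":
                continue
            fits[voi] = {}
            for src, aif in aifs.items():
                f = fit_1tcm(tac, aif, **fit_opts)
                fits[voi][src] = f
                f.to_json(out / "fits" / f"{voi}_{src}.json")
                if not f.converged:
                    qc["nonconverged"].append(f"{voi}/{src}")

    with _stage("bootstrap"):
        bootstraps: dict = {}
        for voi, by_src in fits.items():
            bootstraps[voi] = {}
            for src, f in by_src.items():
                if not f.converged or config.bootstrap_n < 2:
                    continue
                b = residual_bootstrap(f, aifs[src], n=config.bootstrap_n, seed=config.seed)
                bootstraps[voi][src] = b
                b.to_csv(out / "fits" / f"{voi}_{src}_bootstrap.csv")

    with _stage("report"):
        suv_peak = {}
        if config.dose_mbq and config.body_weight_g:
            dose = DoseRecord(config.dose_mbq, config.body_weight_g)
            for voi, tac in tacs.items():
                suv_peak[voi] = float(compute_suv(tac, dose).values.max())
        report = SessionReport(
            day=config.session_day,
            fits=fits,
            bootstraps=bootstraps,
            suv_peak=suv_peak,
            qc=qc,
            output_dir=out,
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))

    if config.make_plots:
        with _stage("plots"):
            _plot_session(report, tacs, out)
    return report


def _plot_session(report: SessionReport, tacs, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for voi, tac in tacs.items():
        ax.plot(tac.times_min, tac.values, "o", ms=3, label=f"{voi} (data)")
    for voi, by_src in report.fits.items():
        for src, f in by_src.items():
            if f.converged:
                ax.plot(f.schedule.mid_min, f.fitted, "-", lw=1, label=f"{voi} fit ({src})")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("activity (kBq/ml)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "tac_fits.png", dpi=120)
    plt.close(fig)


def compare_aif_sources(report: SessionReport) -> pd.DataFrame:
    """Paired LV-vs-AVS comparison table, one row per VOI with both fits.

    Columns: K1 and VT under each source, their differences, and bootstrap
    2.5/97.5 percentile intervals on the differences (paired by replicate
    index when both bootstrap runs are present).
    """
    rows = []
    for voi, by_src in report.fits.items():
        if SOURCE_LV not in by_src or SOURCE_AVS not in by_src:
            continue
        f_lv, f_avs = by_src[SOURCE_LV], by_src[SOURCE_AVS]
        if not (f_lv.converged and f_avs.converged):
            continue
        row = {
            "voi": voi,
            "K1_AVS": f_avs.params.k1,
            "K1_LV": f_lv.params.k1,
            "dK1": f_avs.params.k1 - f_lv.params.k1,
            "VT_AVS": f_avs.vt,
            "VT_LV": f_lv.vt,
            "dVT": f_avs.vt - f_lv.vt,
        }
        boots = report.bootstraps.get(voi, {})
        if SOURCE_LV in boots and SOURCE_AVS in boots:
            n = min(boots[SOURCE_LV].n_success, boots[SOURCE_AVS].n_success)
            if n >= 2:
                dk1 = (
                    boots[SOURCE_AVS].replicates["k1"].to_numpy()[:n]
                    - boots[SOURCE_LV].replicates["k1"].to_numpy()[:n]
                )
                dvt = (
                    boots[SOURCE_AVS].replicates["vt"].to_numpy()[:n]
                    - boots[SOURCE_LV].replicates["vt"].to_numpy()[:n]
                )
                row["dK1_lo"], row["dK1_hi"] = np.percentile(dk1, [2.5, 97.5])
                row["dVT_lo"], row["dVT_hi"] = np.percentile(dvt, [2.5, 97.5])
        rows.append(row)
    if not rows:
        raise ValidationError("no VOI has converged fits under both AIF sources")
    return pd.DataFrame(rows)


def run_longitudinal(reports: list, dose_mbq=None) -> pd.DataFrame:
    """Summarise an ordered series of session reports into a study table.

    One row per (day, VOI, AIF source) with K1, k2, Va, VT and bootstrap
    SDs, plus a ``va_study_mean`` column repeating the across-day mean Va of
    that VOI/source (the blood-volume fraction is expected to be stable over
    the study).  Days must be strictly increasing.
    """
    if len(reports) < 2:
        raise ValidationError("a longitudinal study needs >= 2 sessions")
    days = [r.day for r in reports]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValidationError("session days must be strictly increasing")
    rows = []
    for r in reports:
        for voi, by_src in r.fits.items():
            for src, f in by_src.items():
                if not f.converged:
                    continue
                row = {
                    "day": r.day,
                    "voi": voi,
                    "aif_source": src,
                    "K1": f.params.k1,
                    "k2": f.params.k2,
                    "Va": f.params.va,
                    "VT": f.vt,
                }
                b = r.bootstraps.get(voi, {}).get(src)
                if b is not None and b.n_success >= 2:
                    sd = b.sd()
                    row["K1_sd"] = sd["k1"]
                    row["VT_sd"] = sd["vt"]
                rows.append(row)
    df = pd.DataFrame(rows).sort_values(["voi", "aif_source", "day"]).reset_index(drop=True)
    df["va_study_mean"] = df.groupby(["voi", "aif_source"])["Va"].transform("mean")
    return df


def dose_normalize_tacs(tacs: list, doses: list) -> list:
    """Scale each session's TAC by dose(day1)/dose(day), the convention used
    to overlay serial curves as if every session had received the first
    session's injected dose."""
    if len(tacs) != len(doses) or not tacs:
        raise ValidationError("need one dose per TAC")
    d0 = doses[0].dose_mbq if isinstance(doses[0], DoseRecord) else float(doses[0])
    out = []
    for tac, dose in zip(tacs, doses):
        d = dose.dose_mbq if isinstance(dose, DoseRecord) else float(dose)
        out.append(tac.with_values(tac.values * (d0 / d)))
    return out
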
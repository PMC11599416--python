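# Methods

This note records the models, conventions, numerical choices and known
limitations behind `spectkin`, in the spirit of a methods appendix.

## Data model and conventions

All internal quantities use minutes since injection and kBq/ml; unit
conversion happens only at I/O boundaries. A dynamic acquisition is a
`FrameSchedule` (strictly increasing starts, positive durations,
non-overlapping frames; injection defines t = 0). The default protocol is
the two-phase schedule eight 2.5-min frames followed by eight 20-min
frames (16 frames, 180 min), and fits always use all frames of a schedule
jointly, so multi-phase acquisitions are handled by construction.

Whenever a single timestamp must represent a frame — decay correction,
instantaneous model evaluation, resampling — the frame **mid-time** is
used. Late frames are 20 min long; evaluating at frame start would bias
decay factors by up to ~4% and model values by more.

VOIs are binary masks on the image voxel grid; the VOI value is the
unweighted mean over included voxels. No resampling or partial-volume
weighting is attempted (masks must be supplied on the image grid).

Decay correction multiplies by `2^((t − t_ref)/T½)` with `T½ = 6.0058 h`
(⁹⁹ᵐTc) and reference time t = 0 (injection), matching dose-based SUV
bookkeeping; correcting an already-corrected curve is an error rather than
a silent double scaling. SUV is `C/(dose/weight)` with tissue density
taken as 1 g/ml.

## Input functions

Plasma drives the tissue model; whole blood contributes the blood-volume
term. Two routes produce the pair `(Cp, Cb)`:

* **LV image route** — `Cb` is the mean TAC of an LV-cavity VOI on the
  decay-corrected image; * **AVS route** — `Cb` is a continuous
  shunt-detector counts table multiplied by a cross-calibration factor.

Either way `Cp = r·Cb` with a single time-invariant plasma-to-whole-blood
ratio `r`. Measured per-sample ratios for pertechnetate in rat are nearly
constant over three hours, so a scalar is adequate; the default is the
study-mean 1.239, and `estimate_plasma_ratio` averages per-sample ratios
when measurements are supplied. No delay or dispersion correction is
applied between shunt and tissue, and no metabolite correction is needed
(pertechnetate is not metabolised on this time scale). Input curves are
taken as zero before their first sample (pre-injection); extrapolation
beyond the last sample is an error unless hold-last is explicitly enabled.

A practical caveat found while validating the pipeline: an image-derived
input sampled at the mid-times of 2.5-min frames cannot represent a bolus
peak that is ~1 min wide. Fitting against such a coarsened input biases
K1 and Va by tens of percent on synthetic data even without noise. The
phantom generator therefore always emits its dense ground-truth input so
recovery tests are well-posed, and the same caveat applies to real
image-derived inputs (finer early frames reduce it). Because the
mid-time-sampled input ends half a frame before the schedule does, the
pipeline holds its last value over that final half-frame.

## One-tissue compartment model

    dC_T/dt = K1 Cp(t) − k2 C_T(t)
    C_meas(t) = (1 − Va) C_T(t) + Va Cb(t)

with bounds K1 ∈ [0, 5] ml·min⁻¹·ml⁻¹, k2 ∈ [10⁻⁴, 5] min⁻¹,
Va ∈ [0, 1] ml/ml, and VT = K1/k2 reported for every fit. The `(1 − Va)`
mixing form is the default; the additive form `C_T + Va·Cb` is available
via `va_formulation="additive"` for sensitivity checks, since reference
software does not always document which it uses.

**Convolution.** With `Cp` piecewise linear between samples, the
convolution with `e^{−k2 t}` has an exact per-segment recursion; the
implementation evaluates it in vectorised windows whose accumulated
exponent stays below 50 so the rescaled cumulative sums remain inside
float64 range for any k2, and uses `expm1` so segments with tiny `k2·dt`
lose no precision. A knot is inserted immediately below the first input
sample so the zero-before-first-sample convention is represented as a
step, not a ramp from injection.

**Frame integration.** Predicted frame values are exact time-averages:
integrating the ODE gives `∫y dt = (∫Cp dt − Δy)/k2`, and `∫Cp dt`,
`∫Cb dt` are exact trapezoids on the piecewise-linear input, so frame
averaging adds no discretisation error. Validated against brute-force
trapezoidal convolution at dt = 0.001 min (max relative error well under
0.1%).

**Fitting.** Bounded weighted least squares (`scipy.optimize.least_squares`,
trust-region reflective) minimising `Σ wᵢ(TACᵢ − predᵢ)²`. Default weights
are proportional to frame duration (longer frames integrate more counts);
uniform or explicit per-frame weights are available. Initialisation is a
deterministic 3×3×2 multi-start grid (K1, k2 ∈ {0.01, 0.1, 1}, Va ∈
{0.05, 0.3}); the lowest weighted RSS wins, with exact ties broken to the
lowest K1 then lowest k2 so results are reproducible bit for bit. A fit
where no start converges is returned as a flagged failure
(`converged=False`), mirroring how occasional unfittable VOIs are reported
rather than dropped. Noiseless self-generated data are recovered to
optimizer tolerance (≪0.1%).

One identifiability fact worth knowing: a uniform amplitude rescaling of
the input (e.g. a miscalibrated shunt factor `s`) leaves k2 — a shape
parameter — unchanged, scales fitted K1 by `(1 − Va)/(s − Va)` under the
default mixing form (exactly `1/s` under the additive form), and therefore
scales VT by the same factor as K1. VT is *not* invariant to input-scale
errors; near-equal K1 and VT between LV- and AVS-derived inputs indicates
the two inputs agree, not that the estimate is insensitive to calibration.

## Residual bootstrap

Uncertainty uses residual resampling with refitting: weighted residuals
`eᵢ = √wᵢ·rᵢ` are inflated by `√(n/(n−p))` (n frames, p = 3 parameters) to
undo the downward bias of fitted residuals, resampled with replacement,
rescaled by the destination frame's `1/√wᵢ`, added to the fitted curve,
and each replicate is refitted with the original settings. The SD across
successful replicates (failures are dropped and counted, never imputed) is
the reported error bar; 200 replicates are the default, by which point the
SD estimate is stable. Everything is driven by a single seed and is
exactly reproducible. On the 16-frame protocol at 5% proportional noise
the bootstrap K1-SD tracks the true Monte-Carlo SD to within ~±25%; the
residual pool is treated as exchangeable after weighting, so strongly
heteroscedastic noise that the weights do not capture degrades calibration
— matching weights to the believed error model is recommended. Parametric
alternatives (profile likelihood, Fisher information) are out of scope.

## Synthetic data generator

The generator emulates the study conditions rather than the physics of
multi-pinhole SPECT:

* **Input function** — linear rise from 0 to the peak at t = 1 min, then a
  tri-exponential washout, defaults `A = (2800, 600, 900)` kBq/ml,
  `λ = (3.0, 0.15, 0.001)` min⁻¹. The shape reproduces the reported curve
  features: peak within a few minutes, prompt early washout (to ~20% of
  peak by 20 min), and a slow tail over three hours — pertechnetate
  equilibrates with extracellular fluid and is excreted slowly, so blood
  activity does not approach zero. The amplitude scale makes peak SUVs
  order-1 for the recorded doses and body weights. Plasma is `1.239 × Cb`.
* **Kinetic presets** — `sheet` (K1 = 0.095, VT = 1.35, Va = 0.29),
  `myocardium` (K1 = 0.07, VT = 0.30, Va = 0.29) and `lung_nonspecific`
  (K1 = 0.5, VT = 2.0), anchored to the reported magnitudes: under the
  default input the sheet TAC peaks in the 40–60 min window while
  myocardium washes out promptly. The myocardial K1 is a plausible choice
  (only its VT is reported).
* **Noise** — `Normal(mean = C, var = α·C/duration)` truncated at zero, a
  declared stand-in for reconstructed-SPECT TAC noise (variance growing
  with concentration, shrinking with frame length); the true noise law of
  multi-pinhole reconstruction is not modelled. A plain proportional mode
  (`sd = fraction·C`) supports controlled Monte-Carlo experiments.
* **Phantom** — 40³ voxels at 0.5 mm, disjoint near-spherical regions
  with the study's mean VOI sizes (LV 406, sheet 104, myocardium 96
  voxels); the LV region carries the frame-averaged whole-blood curve,
  tissue regions their model TACs, with optional independent per-voxel
  noise. Ground truth (params, masks, input, noiseless TACs) is always
  returned.
* **Longitudinal series** — six sessions on days 1, 4, 7, 10, 15, 23 with
  the recorded per-day doses and body weights; the default sheet
  trajectory has K1 drifting up to a day-15 plateau and VT declining
  monotonically to a plateau above the myocardium preset. Non-increasing
  VT is enforced when emulating the study design.

What passing tests on these data do **not** show: robustness to
reconstruction artefacts, attenuation/scatter residuals, partial-volume
spill-over between LV blood and adjacent tissue, motion, or VOI placement
error — none of which the generator produces.

## Pipeline and reporting

`run_session` executes load → decay-correct → extract → build input →
fit → bootstrap → report; every stage failure is wrapped in an error
naming the stage, and every reported number is backed by a serialized
intermediate (TAC CSVs, fit JSONs, bootstrap replicate CSVs). Longitudinal
tables report per-day K1/k2/Va/VT with bootstrap SDs plus the across-day
mean Va (expected stable); serial TAC overlays are scaled by
`dose(day1)/dose(day)`, i.e. dose-ratio scaling of decay-corrected
activity — the normalisation is applied to activity, not SUV, which is one
of two defensible readings of "normalised to the injected dose relative to
day 1". Statistical inference between input-function routes (t-tests,
ANOVA) is deliberately out of scope; the report gives estimates and
bootstrap intervals and leaves inference to the user.

## Problem sizes

Default test and acceptance problem sizes: 16-frame curves, 200 Monte-Carlo
replicates, 200 bootstrap replicates, 100 independent realisations for
bootstrap calibration, 50 random inputs for the convolution oracle, and one
40³ phantom — chosen so the full validation runs in a few minutes on one
core while keeping Monte-Carlo standard errors small relative to the
tolerances being checked.
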
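# spectkin

Tracer-kinetic analysis of dynamic SPECT data for reporter-gene cell
tracking — built for studies that follow transplanted NIS-expressing cell
grafts (e.g. cell sheets on an infarcted heart) with serial ⁹⁹ᵐTcO₄⁻
imaging and quantify graft viability through compartment modelling.

## The problem

Cells engineered to express the sodium/iodide symporter (NIS) concentrate
pertechnetate, so a dynamic SPECT scan after a ⁹⁹ᵐTcO₄⁻ bolus shows where
transplanted cells are and how avidly they pump tracer. Turning those
images into numbers requires a pipeline: extract time–activity curves
(TACs) from volumes of interest, correct for physical decay (⁹⁹ᵐTc
half-life 6.0058 h), construct an arterial plasma input function — either
from a left-ventricular (LV) cavity VOI or from an arteriovenous-shunt
(AVS) blood monitor, with a plasma-to-whole-blood ratio correction — fit a
one-tissue compartment model, and track the fitted parameters across
imaging sessions with bootstrap error bars.

## The model

Tissue concentration follows the one-tissue compartment model

    dC_T/dt = K1·Cp(t) − k2·C_T(t),  C_meas(t) = (1 − Va)·C_T(t) + Va·Cb(t)

with `Cp` plasma and `Cb` whole-blood activity concentration, `K1`
(ml·min⁻¹·ml⁻¹) the plasma-to-tissue transfer rate, `k2` (min⁻¹) the efflux
rate, and `Va` (ml/ml) the blood-volume fraction of the VOI signal. The
total volume of distribution `VT = K1/k2` is the equilibrium tissue-to-
plasma ratio and serves as the surviving-cell index: it falls as grafted
cells die or lose membrane transport function. The convolution
`C_T(t) = K1·∫ Cp(s)·e^{−k2(t−s)} ds` is evaluated in closed form on a
piecewise-linear input, and model predictions are exact frame-interval
averages, so no quadrature error enters the fit. Fitting is bounded
weighted least squares over a deterministic multi-start grid; uncertainty
comes from a residual bootstrap with refitting.

Because animal scans are not distributable, the package ships a synthetic
module that generates every input — bolus-shaped input functions, tissue
TACs, count-like noise, 40³-voxel dynamic phantoms with study-sized VOIs,
and a six-session longitudinal series — together with the generating
ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import spectkin as sk

schedule = sk.build_frame_schedule([(8, 2.5), (8, 20.0)])   # 16 frames, 180 min
aif = sk.simulate_aif()                      # bolus input, plasma = 1.239 x blood
truth = sk.KineticParams(k1=0.095, k2=0.095 / 1.35, va=0.29)
tac = sk.simulate_tissue_tac(truth, aif, schedule)
noisy = sk.add_noise(tac, seed=1, model="proportional", fraction=0.05)

fit = sk.fit_1tcm(noisy, aif)
boot = sk.residual_bootstrap(fit, aif, n=200, seed=1)
sd = boot.sd()
print(f"K1 = {fit.params.k1:.4f} +/- {sd['k1']:.4f} ml/min/ml")
print(f"k2 = {fit.params.k2:.4f} 1/min")
print(f"Va = {fit.params.va:.3f} ml/ml")
print(f"VT = {fit.vt:.3f} +/- {sd['vt']:.3f} ml/ml")
```

Output:

```
K1 = 0.0985 +/- 0.0049 ml/min/ml
k2 = 0.0728 1/min
Va = 0.290 ml/ml
VT = 1.353 +/- 0.028 ml/ml
```

The fit recovers the generating high-retention "sheet" kinetics
(K1 = 0.095, VT = 1.35, Va = 0.29) within one bootstrap standard deviation
at 5% measurement noise; the bootstrap SDs are the error bars one would
draw on a longitudinal K1/VT plot.

A command-line layer wraps the same library:

```bash
spectkin simulate --out study/ --seed 1      # synthetic image + masks + truth
spectkin fit --config config.yaml            # single-session analysis
spectkin study --out long/ --seed 1          # 6-session longitudinal run
spectkin compare-aif --config config.yaml    # paired LV- vs AVS-input table
```

Session outputs (TAC CSVs, fit JSONs, bootstrap replicate CSVs,
`report.json`) are written to the configured output directory and are
byte-reproducible from the config and seeds.

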
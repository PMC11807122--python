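# symwm

Simulation and analysis pipeline for a visual-symmetry working-memory
experiment measured with fNIRS.

The scientific question behind the design: does mirror symmetry — a
strong perceptual regularity — make visual patterns easier to hold in
working memory, and which cortical regions carry that advantage? The
paradigm is delayed matching-to-sample: 2 or 4 binary matrix stimuli
flash for 250 ms at vertices of a dodecagon, a 2 s delay follows, and
the participant indicates where the probe stimulus had appeared, while
prefrontal, parietal and occipital hemodynamics are recorded with
dual-wavelength (760/850 nm) fNIRS at 5.08 Hz.

Because the human recordings live elsewhere, this package provides the
*entire computational apparatus* as tested, reusable code, validated by
parameter recovery on synthetic data with known ground truth:

- **Stimuli** — 6×6 binary matrices, 50% black, symmetric (vertical /
  horizontal / diagonal) or asymmetric, with JPEG-compression
  complexity scoring and a Welch t-test of the symmetric/asymmetric
  separation.
- **Task schedule** — 12-location dodecagon geometry, 4 blocks × 72
  trials with exact probe×load balancing, and the 250 ms event stream
  the GLM consumes.
- **Synthetic behavior** — condition-calibrated accuracy, spatially
  structured errors, lognormal reaction times.
- **Behavioral statistics** — RT outlier filtering (mean ± 2 SD),
  error distance and arccos error angle, false-positive rates,
  repeated-measures ANOVA with Greenhouse-Geisser correction and
  generalized η², Bonferroni pairwise contrasts, complexity
  correlations.
- **fNIRS forward simulator** — 116-channel montage (100 long, 16
  short), HRF-convolved condition responses, cardiac / respiratory /
  Mayer-wave physiology, drift, motion artifacts, SNIRF I/O.
- **Preprocessing** — optical density, scalp coupling index and
  coefficient-of-variation quality control, temporal derivative
  distribution repair (TDDR), modified Beer-Lambert conversion
  (partial pathlength factor 1).
- **Subject-level GLM** — canonical double-gamma HRF with temporal and
  dispersion derivatives, cosine drift to 0.03 Hz, short-channel and
  ECG/SpO2 nuisance regressors, AR(1) prewhitening, contrasts, ROI
  aggregation.
- **Group inference** — random-intercept linear mixed models
  (probe × load), ICC and Nakagawa marginal/conditional R²,
  channel-wise contrasts with Benjamini-Hochberg FDR, Tukey/Bonferroni
  post-hocs.
- **Power** — noncentral-F repeated-measures power and sample-size
  search, λ = f²·n·m/(1−ρ).

The model at the core of the hemodynamic analysis is the prewhitened
GLM: for channel c and chromophore k (HbO/HbR),

    y_ck = X β_ck + ε,   ε_t = ρ ε_{t−1} + ν_t,

with X containing the HRF-convolved condition regressors and nuisance
terms; β̂ is the GLS estimate after exact AR(1) whitening, and group
effects follow β_ROI ~ probe * load + (1 | subject).

## Worked example

```bash
python examples/power_analysis.py
```

prints

```
smallest n for 95% power (f=0.25, m=4, rho=0.5, alpha=0.05): 36
power at n=26 under the same specification: 0.851
```

i.e. 36 participants are needed a priori to reach 95% power for a
medium within-subject effect, and the reduced 26-subject sample retains
~85% power.

```bash
python examples/fnirs_parameter_recovery.py
```

runs one synthetic subject through the full chain and prints, among
other numbers,

```
channel QC: kept 110/116 (subject excluded: False)
symmetry x load interaction by ROI group (µM):
  dlPFC           4.14   (planted)
  OFC             4.26   (planted)
  ...
  motor           0.30   (control)
  early_visual   -0.15   (control)
```

— the planted symmetry×load interaction is recovered in the task ROIs
and absent from the motor / early-visual controls. The other scripts in
`examples/` cover stimulus complexity, the behavioral ANOVA, and group
mixed-model inference, one capability each.

## Layout

```
src/symwm/        library (stimuli, schedule, synth_behavior,
                  behavior_stats, montage, synth_fnirs, preprocess,
                  glm, group, power, snirf_io, config, pipeline)
examples/         one narrative script per capability
tests/            pytest suite incl. acceptance checks
docs/methods.md   model, assumptions, parameter choices, limitations
```
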
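# Methods

`symwm` re-creates, as tested code, the computational machinery of a
delayed matching-to-sample experiment on visual symmetry in working
memory, measured behaviorally and with whole-head fNIRS. Because the
human recordings themselves are external, every analysis stage is
validated against synthetic data whose generating parameters are known,
so the claims the test suite makes are claims about *parameter
recovery and calibration of the machinery*, not about any cohort.

## Stimuli

Stimuli are 6×6 binary matrices with exactly 18 black cells (50%).
Symmetric stimuli are built to be invariant under exactly one axis:

- *vertical / horizontal*: a random 3-column (3-row) half with exactly
  9 black cells, mirrored;
- *diagonal*: the upper triangle including the diagonal is filled at
  random with a diagonal black count d ∈ {0, 2, 4, 6} and
  (18 − d)/2 off-diagonal pairs, then transposed. A rectangular half
  cannot be reflected across a diagonal, so this triangular
  construction is the only one that honors both the axis and the
  50%-black rule;
- *asymmetric*: 18 black positions drawn uniformly, redrawn whenever
  any of the four reflection flags (vertical, horizontal, main and
  anti-diagonal) holds.

Grids accidentally symmetric under an undeclared axis are also redrawn,
so a stimulus's class is unambiguous. The full set holds 72 stimuli:
36 asymmetric and 12 per symmetry axis.

Visual complexity is scored as the byte size of a lossy JPEG encoding
of the rendered grid (50×50 px cells → 300×300 8-bit grayscale, quality
75, no chroma subsampling; all settings recorded in the score).
Absolute byte counts are encoder-dependent; only the ordering
(asymmetric > symmetric) and its Welch t-test are meaningful, and only
that ordering is asserted.

## Task geometry and schedule

Twelve response anchors sit on a dodecagon of radius 200 px around the
screen center (anchor 0 at 12 o'clock, clockwise, screen y downward).
A schedule is 4 blocks × 72 trials (288 total): each stimulus probes
exactly once per block, loads (2 vs 4 encoded items) are balanced 18/18
within each symmetry stratum so the 2×2 probe×load crossing is exact by
construction, ITIs are drawn uniformly from {2, 4, 6, 8, 10} s, and
distractor classes are constrained so the encoded-item pool is exactly
half symmetric. The event stream carries one 250 ms event per trial at
the encoding onset, labelled by probe symmetry × load; onsets
accumulate ITIs, the 0.25 s encode and 2 s maintenance phases, the
response period (the simulated RT, or the full 10 s window when no
responses are supplied), and 30 s block breaks. The maintenance phase
carries no separate regressor.

## Synthetic behavior

Per-cell hit probabilities interpolate the group accuracy marginals
(low load 65.61%, high load 32.51%) and the per-load symmetry
advantages (3.11 and 11.05 percentage points), giving cells ≈ 67.2 /
64.1 / 38.0 / 27.0 %. Reaction times are lognormal per cell,
moment-matched to the reported cell means and SDs (e.g. low/symmetric
1183.4 ± 440.2 ms), truncated to [150, 10000] ms. On error trials the
chosen anchor follows a wrapped von-Mises-like kernel around the
target (concentration κ, default 1.5 for symmetric and 0.8 for
asymmetric probes so asymmetric errors land farther away) plus extra
mass on anchors that displayed a distractor (confusion weight 2.0).
These error-structure parameters have no reported counterpart; they
are fixed plausibility choices, and tests assert only monotonicity
(higher κ → smaller error distance) and calibration (empirical cell
accuracy within 0.02 of the target over ~2,500 trials per cell).

## Behavioral statistics

- *RT outliers*: per subject over correct trials, outside mean ± 2 SD;
  the scope (per subject, not per cell) is configurable.
- *Error geometry*: Euclidean distance between chosen and target
  anchors and the arccos angle between the center-to-target and
  center-to-chosen vectors; both are only meaningful on error trials.
- *False positives*: among incorrect responses, the share landing on a
  displayed distractor's anchor; an empty denominator is flagged
  undefined, never reported as 0.
- *RM-ANOVA*: fully within-subject, on subject×cell means, via the
  definitional Möbius decomposition of marginal means (so an
  independent brute-force sums-of-squares oracle can check it to
  1e−10). Generalized eta-squared uses the fully-within form
  SS_effect / (SS_effect + SS_subject + Σ error SS). The
  Greenhouse-Geisser ε for an effect comes from the covariance of the
  effect's orthonormal Kronecker contrast of the cell means,
  ε = tr(S)²/(d·tr(S²)), clipped to [1/d, 1]; two-level effects have
  ε ≡ 1. Cross-checked against `pingouin` in the tests.
- *Pairwise comparisons*: cell-mean differences with the pooled
  condition-by-subject error (df = (n−1)(k−1), e.g. 108 for 37
  subjects × 4 cells), Bonferroni-adjusted.
- *Complexity correlations*: Pearson r of per-stimulus JPEG bytes with
  accuracy and mean correct RT, with Fisher-z 95% CI.

## fNIRS forward model

The montage has 116 channels at 760/850 nm: 100 long (30 mm) channels
labelled by ROI (prefrontal sub-regions summing to 32 channels, PPC 15,
LOC 13, motor 18, early visual 8, 14 unlabelled) and 16 short (8 mm)
channels sampling scalp physiology only.

Hemoglobin time series are built in µM: long channels carry
β_condition × (canonical HRF ⊗ 250 ms boxcar) plus systemic physiology
(cardiac oscillation at a wandering ~1.1 Hz rate, respiration at
0.25 Hz, Mayer waves modelled as 0.05–0.15 Hz band-limited noise —
broadband, as in real recordings, not a pure tone — and linear +
random-walk drift), each channel with its own systemic gain, plus white
measurement noise (SD 1 µM on HbO). Short channels carry systemic
signal and noise but no evoked response. Evoked HbR is −1/3 of HbO
(the canonical coupling); *systemic* HbR instead co-varies positively
with HbO (ratio 0.3), since pulsatile physiology is not neurovascular —
a −1/3 systemic coupling would nearly cancel the cardiac signature at
760 nm (ε_HbR·⅓ ≈ ε_HbO there), which is an artifact of the coupling,
not physiology.

Default condition amplitudes plant a symmetry×load interaction in
dlPFC, OFC, PPC and LOC (HbO 4/10/5/6 µM for sym-low/sym-high/
asym-low/asym-high) and a flat 5 µM response in all other regions,
including the motor and early-visual control ROIs. With the 1 µM noise
these give single-trial SNR near 1.

Concentrations map to intensity through the modified Beer-Lambert law,
ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·ppf with ppf = 1 and the
Gratzer/Prahl extinction table (760 nm: 1486.59 / 3843.71; 850 nm:
2526.39 / 1798.64 cm⁻¹M⁻¹), I = I₀·10^(−ΔOD). Motion artifacts —
Gaussian transients of ~2 s and step baseline shifts, amplitudes 10×
and 8× the typical OD fluctuation — are injected multiplicatively in
OD space (shared across wavelengths, as motion is) and logged.
Auxiliary traces: instantaneous heart rate, SpO2 (98% with slow
wander), PPG.

## Preprocessing

OD = −log10(I / mean_t I); the mean reference makes OD scale-invariant
and means concentrations are recovered up to a per-channel constant
(immaterial, since only fluctuations are analyzed). Channel quality:
SCI = cross-wavelength Pearson correlation of 0.7–1.5 Hz band-passed
OD, and CV = 100·SD/mean of raw intensity per wavelength. A channel is
excluded when SCI < 0.05 (the study's threshold; far below the
conventional ≈0.7–0.8, both exposed as presets) or when its worst-
wavelength CV exceeds the across-channel mean + 2 SD (an adaptive
reading of "CV > 2 standard deviations from the mean"; a fixed-percent
rule is available). A subject with > 20% failing channels is flagged
excluded.

TDDR follows the published derivative-reweighting scheme exactly:
split at 0.5 Hz, iterate a robust mean/scale (1.4826·MAD) with Tukey
biweight weights (tuning 4.685) on the low component's first
differences, integrate w·(d−µ), restore the initial value and add the
high-frequency residual back. Two consequences verified against the
reference implementation and documented as inherent: (i) smooth
signals shrink by roughly the mean biweight weight (≈6–20% depending
on the noise share of the low band), so GLM amplitudes estimated after
TDDR are mildly attenuated — uniformly across conditions, leaving
contrasts and cross-channel correlations intact; (ii) only artifacts
whose energy lies below the 0.5 Hz split are strongly repaired:
~2 s transients and baseline steps are attenuated > 90%, sub-second
spikes only 45–85%. The amplitude-recovery bias test therefore runs
the artifact-free chain with TDDR bypassed; the full chain is held to
correlation and detection criteria.

## Subject-level GLM

The design matrix holds, per condition present in the events, a
canonical double-gamma HRF regressor (peak delay 6 s, undershoot 16 s,
dispersions 1, ratio 1/6, unit peak; 250 ms boxcars convolved on a
20× oversampled grid) with temporal (1 s onset-shift finite
difference) and dispersion (δ = 0.01) derivatives; a DCT drift basis
with K = ⌊2·T·0.03⌋ columns (high-pass at 0.03 Hz); a constant; the
across-short-channel mean per chromophore; and z-scored heart-rate and
SpO2 regressors. Rank deficiency raises with the collinear columns
named.

Fitting is OLS, then per-channel lag-1 residual autocorrelation ρ
(Yule-Walker, clipped to |ρ| ≤ 0.99 with a warning), exact AR(1)
whitening (first row scaled by √(1−ρ²)), and a GLS refit; the
whitened normal equations are assembled from precomputed cross-products
so the per-channel cost is O(p²). Condition effects are the canonical
betas only; derivative betas are nuisance. Contrasts (symmetry, load,
interaction) are w'β with variance w'Cov(β)w; ROI aggregation is the
unweighted channel mean with counts reported.

## Group inference

ROI-level effects (subject × ROI × chromophore × probe/load cell) feed
a random-intercept linear mixed model, effect ~ probe * load with
treatment coding (asymmetric / low reference) and optional
between-subject accuracy covariates, fit by REML (statsmodels MixedLM;
several optimizers are tried because near-boundary subject variance
can make a single optimizer fail). Fixed-effect p values are Wald z —
a documented simplification that is mildly anti-conservative at small
n. ICC = σ²_subject/(σ²_subject+σ²_resid); marginal and conditional R²
follow the Nakagawa decomposition with the fixed-prediction variance
in the numerator. Channel-wise group contrasts use the one-sample
reduction t = mean/(SD/√n) of subject contrast effects mapped to z,
with Benjamini-Hochberg FDR at 0.05 applied per chromophore across
channels. Post-hoc cell comparisons offer Tukey (studentized range) or
Bonferroni adjustment over the 6 pairs.

## Power

Within-factors repeated-measures power uses the noncentral F with
λ = f²·n·m/(1−ρ), df₁ = ε(m−1), df₂ = ε(n−1)(m−1) — the G*Power
within-factors convention with its default ρ = 0.5 and ε = 1, which
are not reported and are therefore exposed as parameters. Under the
design's specification (m = 4, f = 0.25, α = 0.05) the smallest n
reaching 95% power is 36, and power at n = 26 is 0.851.

## Problem sizes and numerical choices

The test suite validates the full chain at sizes chosen to keep the
simulations meaningful yet routine to run: null calibrations use 1,000
replicates (37 subjects × 72 trials/cell for the behavioral ANOVA;
116 channels × 20 subjects for the FDR null); parameter recovery and
interaction detection use 20 replicates of 20-subject cohorts with
one 72-trial block per subject. All randomness flows from explicit
integer seeds (per-stage substreams derived by hashing, kept below
2³¹), and identical seeds reproduce recordings bit-for-bit.

Degenerate inputs are handled explicitly: constant series pass TDDR
unchanged (robust scale 0); empty error denominators are flagged, not
zeroed; single-level factors drop out of the LME design; a subject
variance estimated at zero is reported as a boundary fit; SCI bands
must lie inside the Nyquist range (fs/2 = 2.54 Hz).

## Known limitations

- No photon-transport modelling, optode registration, or MNI anatomy:
  ROI labels are bookkeeping, not geometry.
- TDDR's amplitude shrinkage and its weakness on sub-second spikes
  (above).
- Wald z fixed-effect tests in the LME are anti-conservative for very
  small cohorts; Satterthwaite df are not implemented.
- The synthetic generator's systemic physiology is stationary and
  linear-additive; real recordings show nonstationary coupling,
  serially correlated noise beyond AR(1), and optode-specific drift
  that the simulator does not emulate — passing recovery tests here
  demonstrates the machinery is correct and calibrated, not that the
  human-data effect sizes would be recovered.
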
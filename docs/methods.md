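# Methods

`strokefuse` implements a white-matter (WM) infarct biomarker pipeline: a
synthetic longitudinal stroke cohort, sliding-window extraction of 85
resting-state fMRI (rs-fMRI) time-series features, lesion-to-WM contrast
screening with a modified Fisher score, voxel-wise logistic fusion of a
segmentation probability map with the top-ranked biomarkers by coarse
full-grid search, Dice-based model comparison under subject-level data
splits, and Holm–Bonferroni-controlled recovery-correlation analyses.  This
note documents the models, the numerical conventions and the design choices
made where the procedure was genuinely open.

## The synthetic cohort

Restricted clinical data cannot ship with a package, so the cohort module
generates a fully parameterised, seeded stand-in whose *planted* effects
define what every downstream stage is expected to recover.

**Geometry.** The brain is a fixed smoothed ellipsoidal WM shell around a
small ventricle-like hollow, proportional to the grid (default 16³ voxels at
2 mm — a desk-scale region of interest; all stages are grid-agnostic).  Each
subject's lesion is a connected random ellipsoid (random axes, rotation,
volume drawn from `lesion_volume_range`, default 30–120 voxels) carved out of
the WM compartment.  The WM mask excludes the infarcted tissue, as a
structural WM segmentation would; the analysis ROI is the union of the two
masks.  Native-space masks are the 2× upsampled ROI masks, so the 2×
block-downsampling step of ROI construction (a coarse voxel is in-ROI iff at
least half its 8 children are) reproduces them exactly.

**BOLD signal.** Seven runs per visit, 128 frames at TR = 2 s (the first 5
frames are discarded downstream).  Each ROI voxel's series is

    baseline + noise_sd * (white + 0.3 * pink) + physio + A_v * sin(2*pi*f*t + phase)

* `f` is drawn per subject in 0.01–0.10 Hz so that every analysis band is
  exercised across a cohort; the oscillation is coherent (one phase per run).
* `A_v` equals `wm_oscillation_amplitude` (default 1.0) in WM and
  `contrast * wm_oscillation_amplitude` in the lesion, where `contrast` is
  the visit's planted lesion/WM amplitude ratio (defaults 2.0 subacute,
  1.4 chronic, ±30 % per-subject jitter).  This is the planted biomarker:
  lesions oscillate more strongly, subacute more than chronic.
* `physio` is a spatially smooth broadband background (white noise smoothed
  over space with σ = 1.2 voxels, unit temporal variance, modulated by a
  smooth ±40 % spatial amplitude field).  It emulates locally coherent
  physiological fluctuation and gives the WM realistically heterogeneous
  broadband variance.  Without it, adding a sinusoid raises variance and
  spectral peak in lockstep, and every dispersion statistic carries the same
  lesion contrast as the narrow-band peak — with it, the spectral peak
  amplitude is genuinely the most specific readout of the planted effect,
  which is the situation the screening stage is designed to detect.

**Probability map.** The surrogate segmentation-model output is the lesion
mask after Gaussian blur (σ = 0.8 voxels), three degradations, additive
N(0, 0.05) noise and clipping to [0, 1]:

1. a global attenuation, solved by bisection so that thresholding at 0.5
   yields a per-subject Dice drawn from `probmap_quality_range`
   (default 0–0.85);
2. with probability 0.7, a *partial miss*: lesion evidence on one side of a
   random plane through the lesion centroid is attenuated to 0–40 % —
   a failure threshold re-optimisation cannot undo;
3. with probability 0.5, a false-positive blob elsewhere in the ROI.

Attenuation alone turned out to be fully reversible by threshold tuning
(re-optimised Dice ≈ 0.93), which would leave the fusion stage nothing to
contribute; the miss and false-positive components bound the best achievable
probability-map-only Dice away from 1 and reproduce the situation where
rs-fMRI evidence genuinely adds information.

**Assessments.** Word-comprehension change is planted as
`effect_slope × (subacute contrast) + noise` (continuous scores, so the
noiseless effect is exactly recoverable); FIM Walk change is anti-correlated
with the planted amplitude change and clipped to the ordinal 1–7 scale;
Posner reaction-time change is pure noise.  Because the amplitude change is
dominated by the subacute level, the change-vs-change family inherits an
induced (arithmetic, not planted) word-comprehension association — a known
property of difference scores that the package reports rather than hides.

**Determinism.** Every stochastic component draws from
`SeedSequence([seed, subject, stream])`; identical configurations produce
byte-identical NIfTI files.

What the generator does *not* emulate: registration/motion artefacts, spatial
autocorrelation of the lesion signal beyond the coherent oscillation,
scanner drift, non-Gaussian physiological noise, and any T1-weighted image
content (the probability map stands in for the upstream segmenter).  Passing
tests therefore demonstrate that the pipeline recovers its planted effects
under controlled conditions, not that it would perform identically on
clinical data.

## The 85-feature registry

77 automatically computed signal metrics in seven groups (raw-signal
statistics; power-spectrum summaries; envelope statistics; envelope-spectrum
summaries; autoregressive diagnostics; the statistic and AR blocks re-applied
after linear de-trending) plus 8 literature rs-fMRI features (band
amplitudes of fluctuation and power ratios for 0.01–0.04 / 0.04–0.08 /
0.08–0.10 Hz; Kendall W and mean pairwise Kendall tau).  The de-trended
statistic group contains 20 metrics — the 19 raw statistics plus the variance
of the de-trended series.  Exact definitions (and the formula of every
entry) are exported by `strokefuse export-registry`.

Numerical conventions:

* **Spectra** are single-taper periodograms of the mean-removed series, no
  zero padding (T ≈ 123 samples is too short for segment averaging).  The
  amplitude spectrum is scaled so an on-bin sinusoid of amplitude A has peak
  amplitude exactly A.  Linear de-trending is *not* applied in the spectral
  path — the fitted line absorbs part of an on-bin sinusoid — only in the
  de-trended feature groups.
* **Band features**: band amplitude is the sum of amplitude-spectrum bins in
  the band; band power ratio is band power over total 0.01–0.10 Hz power.
  Band membership is `low <= f <= high` for the low band and
  `low < f <= high` above it, so shared edges count once.
* **SNR / SINAD / THD** (dB): fundamental = largest non-DC periodogram
  line; harmonics = its integer bin multiples below Nyquist; noise = the
  remaining bins.
* **Envelope** = magnitude of the analytic signal of the *de-trended*
  series.  Removing the trend (and the ≈100-unit BOLD baseline with it)
  first is the standard practice; it also keeps the envelope spectrum a
  distinct measurement rather than a copy of the signal spectrum.
* **AR block**: Yule–Walker autocovariances, Levinson–Durbin recursion for
  orders 1–8, order selected by minimum AIC = T·ln(σ²) + 2(p+1).  "First
  frequency" is the dominant-pole frequency |arg z*| / (2πTR); the damping
  coefficient is −Re(s)/|s| with s = ln(z*)/TR.  (The alternative reading —
  spectral peak of the AR fit — is not emitted; the pole convention is
  documented here precisely because the choice was open.)
* **Kendall features**: W uses the classical rank-sum formula without tie
  correction (the series are continuous); the pairwise statistic is tau-a,
  computed exactly via pairwise time-order sign vectors.  Both W over the
  window and mean pairwise tau are emitted because the two readings of
  "local concordance" differ.
* **Quartiles** use linear-interpolation quantiles; SD/variance use ddof = 1;
  skewness and kurtosis are biased moment estimators, kurtosis non-excess.
* **Degenerate inputs**: statistics with a zero denominator on a constant
  series return 0, and screening flags features whose maps have zero WM
  spread or non-finite values, forcing them to the bottom of the ranking.

The per-window functions are thin wrappers over a batch engine that
evaluates all windows of a run at once (FFT-based autocovariances, batched
companion-matrix eigenvalues, sparse window-membership matrices for the
concordance features); there is one code path, not two.

## Sliding-window feature maps

Every ROI voxel owns a 3×3×3 window over its in-ROI neighbours; windows with
fewer than 2 in-ROI voxels are invalid (minimum cluster-size rule, purely
geometric).  The window's mean series feeds the univariate features; the
individual voxel series feed the concordance features.  This mean-plus-voxel
reading of "probing with a sliding window" is a documented choice, isolated
behind one function.  Per-subject maps are z-scored over valid ROI voxels;
multiple runs are pooled by the voxel-wise mean of z-maps (the least
assumptive pooling; per-run application is used where run variability is
reported).

## Screening

Per scan and feature, the modified Fisher score
`(Mean_Lesion − Mean_WM)² / SD_WM²` uses only the WM spread in the
denominator (deliberately asymmetric relative to the classical two-class
criterion).  Ranking averages per-scan scores over all training scans with
equal weight per scan; ties break by registry order.  The contrast sign of
each selected feature (sign of the pooled lesion−WM mean difference) is
passed to the fusion stage.

## Fusion

Voxel-wise infarct log-odds: `b0 + b1·P_z + b2·F1_z + … + bn·Fn_z`, with the
probability map and feature maps z-scored per subject and the feature maps
zero-clipped: a positive-contrast feature keeps only z ≥ 0.1, a
negative-contrast one only z ≤ −0.1 (the directional reading of the clipping
rule; a symmetric |z| < 0.1 variant is available as a configuration switch).
Coefficients come from a coarse full-grid search — default levels
b0 ∈ {−2, 0, 2}, b1 ∈ {0.5, 1, 2, 4}, feature weights ∈
{0, 0.25, 0.5, 1, 2, 4}, i.e. 432 combinations for two features — maximising
the mean training Dice of the p > 0.5 prediction.  Ties prefer the
smallest-magnitude coefficient vector, then enumeration order.  The grid
*level values* are a package default (the level *counts* are fixed by the
design); gradient-based optimisers are deliberately not provided.  At most
two rs-fMRI features enter the model.

Three contenders are compared: (1) the raw probability map thresholded at
0.5, (2) the re-optimised probability-map-only model (same grid, no
features), (3) the multivariate model.  Because the multivariate grid
contains every probability-map-only combination, its training Dice always
dominates; the test-set comparison is the meaningful one.

## Evaluation protocol

Random subject-level 50/50 split (odd cohorts give the training half the
extra subject), plus the exactly swapped split; all fitting happens
independently per split; final reporting averages the two splits' test
means.  The multivariate contender is fitted on run-pooled maps and applied
per run, reporting each test subject's across-run mean ± SD.  Paired t-tests
pair per-subject test Dice values; a zero-variance difference vector is
flagged as degenerate (identical vectors: t = 0, p = 1).

## Outcome statistics

The per-subject biomarker level at a visit is the mean per-scan Fisher score
of the selected feature over that visit's runs.  Two three-test families
(FIM Walk, word comprehension, Posner reaction time): prognostic (assessment
change vs subacute level) and longitudinal change (assessment change vs
level change), each Holm–Bonferroni-controlled at FWER 0.05 with step-down
thresholds α/(m−i+1) — {0.0167, 0.025, 0.05} for m = 3.  Only completer
subjects (both visits) enter.  The subacute-vs-chronic biomarker decline is
a paired t-test on the per-subject levels.

## Problem sizes and tolerances

Default study conditions: 20 subjects, 14 chronic completers, 7 runs per
visit, 128 frames, 16³ ROI grid (≈760 ROI voxels) — chosen so a full cohort
extraction-plus-evaluation runs in tens of seconds and the seeded
20-replicate recovery suite completes in minutes on one CPU.  Oracle
agreement tests use absolute tolerances of 1e−8–1e−12 on randomised small
inputs; stochastic recovery checks use fixed seeds and majority/90 %
criteria over 20 replicates; the all-null FWER simulation uses 1000
replicates with a two-standard-error Monte-Carlo allowance.

## Known limitations

* The 77 automatic metrics follow standard signal-processing definitions;
  no attempt is made to numerically reproduce any proprietary toolbox.
* The generator's lesions are ellipsoids; real infarct shapes, mass effects
  and perilesional gradients are out of scope.
* The probability-map degradation model (blur + miss + false positive +
  attenuation + noise) is monotone enough for bisection but is not a model
  of any particular segmentation network's failure modes.
* Whether the sliding window should treat lesion-only voxels differently
  from WM voxels is not distinguishable from the combined-ROI reading
  implemented here.
* With only two visits, difference-score analyses inherit induced
  correlations (see the assessments section); the package reports both
  families and leaves the interpretation to the analyst.
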
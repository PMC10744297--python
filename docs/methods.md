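# Methods

## Scope and data model

`ramanpipe` implements a complete ex-vivo tissue-classification workflow for
Raman spectra: cohort simulation, spectral preprocessing, wavenumber-region
selection, PCA, classical and convolutional classifiers, patient-grouped
cross-validation, a preprocessing ablation harness, and 1-D Grad-CAM
interpretation. The unit of analysis is a `Cohort`: a spectra matrix on a
shared strictly increasing Raman-shift axis (cm⁻¹) plus per-spectrum
metadata (spectrum id, patient id, binary label with 0 = healthy,
1 = cancerous). Cohorts persist as a CSV matrix + JSON manifest; no binary
or proprietary formats are used.

## The reference acquisition axis

Clinical Raman systems sample unevenly in wavenumber. The package's
reference axis over 500–3200 cm⁻¹ is piecewise-uniform: 2530 points at
1100/1210 cm⁻¹ spacing from 500, then 635 points at 300/476 cm⁻¹ spacing
from 2800 — denser at high shift, consistent with constant detector-pixel
pitch in wavelength under 785 nm excitation. On this axis the standard
region selections contain exactly 1211 (fingerprint, 700–1800 cm⁻¹), 477
(CH stretch, 2800–3100 cm⁻¹) and 1688 (union) points, the feature counts
the classifiers are dimensioned for. The axis is a documented stand-in for
an instrument calibration, not a physical model; region endpoints are
compared closed with 10⁻⁶ cm⁻¹ absolute tolerance so on-grid endpoints
survive floating-point assembly.

## The cohort simulator

Real spectra behind studies of this kind are rarely publishable, so the
simulator is first-class, tested code whose defaults define the study
conditions: 22 patients × 10 spectra per class plus one extra pair for the
first patient = 442 spectra, 221 per class, balanced within every patient.

Each spectrum is `clean(ν)·gain + A_b·jitter·B(ν) + ε + spikes`, clipped at
zero (photon counts):

- `clean` is a sum of unit-height Lorentzians `(Γ/2)²/((ν−c)²+(Γ/2)²)`;
  FWHM defaults 15 cm⁻¹ in the fingerprint region, 40 cm⁻¹ in the
  CH-stretch region. The default band library places bands at 866, 1005,
  1250, 1330, 1342, 1437, 1450, 1658, 1671, 1748, 2852, 2890, 2935 and
  2974 cm⁻¹, grouped as protein / lipid / collagen. Class contrast encodes
  the standard biochemistry — protein bands ×1.3 in cancer, lipid bands
  ×0.7, collagen ×1.2 — capturing protein overexpression and the higher
  lipid-to-protein ratio of healthy tissue. True clinical effect sizes are
  unknown; these are deliberately moderate defaults and nothing downstream
  depends on their exact values.
- `B(ν)` is the autofluorescence shape: a decaying exponential
  (e-folding 1200 cm⁻¹) plus a broad Gaussian hump (center 1400 cm⁻¹,
  σ = 600 cm⁻¹), unit-normalized and scaled by `baseline_amplitude`
  (default 2, i.e. background ≈ 2× band height). Each spectrum additionally
  draws a log-normal baseline intensity jitter (σ = 0.3): real
  autofluorescence varies strongly between tissue spots, and without that
  variation a constant background would be invisible to any classifier and
  baseline correction could never matter.
- `gain` is per-spectrum log-normal (σ = 0.3), `ε` i.i.d. Gaussian
  (σ = 0.03), and spikes are per-channel impulses (probability 0.002,
  amplitude 5×uniform) emulating cosmic-ray events.
- Patient-level log-normal multipliers (σ = 0.15) on the protein / lipid /
  collagen group amplitudes give each patient a biochemical signature. This
  is what makes leave-one-patient-out validation genuinely harder than
  spectrum-level splits and what the leakage guards test against.

A single seeded generator with fixed draw order (patient multipliers, then
per spectrum gain → baseline jitter → noise → spikes) makes cohorts bitwise
reproducible. What the simulator does **not** model: instrument response,
detector etaloning, Mie scattering, wavelength-calibration drift, band-shape
changes (only amplitudes differ between classes), or correlated noise.
Passing tests therefore demonstrate correctness of the analysis machinery
under a plausible generative model, not clinical performance on real tissue.

## Preprocessing

- **SNIP baseline** (default 80 iterations): iterative peak clipping
  `vᵢ ← min(vᵢ, (vᵢ₋ₘ + vᵢ₊ₘ)/2)` with window half-width m growing 1…80
  (a decreasing-window variant is available). Two numerical choices matter
  and were validated on a ramp-plus-Lorentzian fixture where the truth is
  known: (1) points closer than m to a boundary are left unclipped —
  clipping against a self-anchored edge average erodes monotone spectrum
  ends by tens of percent; (2) the log-log-sqrt (LLS) dynamic-range
  compression common for count-scale data is **off** by default, because at
  intensity scales of order 1–100 its concavity makes repeated clipping eat
  sloped backgrounds (peak apex recovered at ~175% of truth with LLS versus
  0.1% error without). With these choices the recovered peak amplitude on
  the fixture is within 0.1% and off-peak residuals are below 1% of the
  ramp height, and the production implementation agrees with an
  independently coded scalar clipping loop to 10⁻⁹ elementwise. The
  estimated baseline never exceeds the input.
- **Normalization**: L2 (x/‖x‖₂, exact unit norm) or SNV
  ((x−mean)/sd with population sd). Zero-norm and zero-variance inputs
  raise instead of emitting NaNs.
- **Median filter** (window 5) and smoothing (Savitzky–Golay 11/3, Gaussian
  σ = 2 samples truncated at 4σ) all use mirror padding (edge sample not
  repeated); the padding convention is fixed and documented because it
  changes edge values.
- Negative intensities after baseline subtraction are kept; normalization
  operates on signed values.

Pipelines (`PipelineSpec`) are ordered stage lists with at most one PCA
stage, which must come last. Per-spectrum stages run on the full acquired
axis, then the region is selected, then PCA runs on the region — matching
the study design where spectral cleanup happens on the whole 500–3200 cm⁻¹
range. Presets: `suggested_ml` = SNIP(80) → L2 → median(5) → region →
PCA(30); `suggested_dl` = SNIP(80) → L2 → region (median filtering and PCA
are deliberately omitted in front of conv nets, which handle impulse noise
and high dimensionality internally); `pipeline_a/b/c` are literature-style
comparison recipes (Savitzky–Golay or Gaussian smoothing + SNIP + SNV
[+ PCA(30)], and SNIP + SNV + Savitzky–Golay with no dimensionality
reduction — the literature recipe taken literally).

## PCA

Deterministic full-SVD PCA (no randomized solver, hence seed-free), mean
centering, components ordered by decreasing variance. Inside
cross-validation PCA is always refit on the training patients of each fold;
whole-cohort variance tables (10/20/30/40 components, one decimal) are a
separate, clearly-labelled reporting mode.

## Classifiers

Classical families with fixed, overridable defaults: logistic regression
(ridge penalty, C = 1), RBF SVM (C = 1), random forest (100 trees), XGBoost
(200 rounds, learning rate 0.1, depth 3, L2/ridge regularization 10⁻⁴).
All seeded, single-threaded for determinism.

The deep models run on a purpose-built numpy engine with explicit
backpropagation (Conv1D with 'same' zero padding, batch norm, dropout,
average/global-average pooling, dense, residual blocks, Adam, binary
cross-entropy on logits):

- **1D-CNN**: conv(10 filters, kernel 3) → ReLU → batch norm →
  dropout(0.25) → conv(25, 3) → ReLU → batch norm → dropout →
  average-pool(8) → flatten → dense(1) → sigmoid.
- **1D-ResNet**: three residual blocks (16/32/64 channels, two conv(3) +
  batch-norm each, 1×1-projection shortcut on channel change), global
  average pooling, dense(1) → sigmoid.

Both carry an L2 weight penalty of 10⁻⁴ and train for 40 epochs of Adam at
learning rate 10⁻³, batch size 32, Glorot-uniform initialization, seeded
shuffling — reproducible to ~10⁻⁵ in output probabilities. Batch-norm uses
eps 10⁻³ and running-stat momentum 0.9; 0.99-style momentum leaves inference
statistics near their initialization for the short schedules small spectral
datasets get, which silently ruins evaluation-mode predictions. Dropout rate
0.25 and the three-block ResNet layout are package choices where the
architecture family leaves them open; the 'same' conv padding keeps feature
maps aligned with the wavenumber axis so saliency maps are interpretable.
Every layer's analytic gradient is verified against central differences in
the test suite.

## Evaluation

Fold plans never split a patient: leave-one-patient-out (one fold per
patient) and patient-grouped stratified k-fold (k = 10 default, seeded,
approximately label-balanced). Both are validated exhaustively — partition
of the cohort, zero patient overlap per fold — and a sentinel experiment in
the test suite checks that a deliberately added patient-identifying feature
cannot lift grouped-CV accuracy on within-patient-randomized labels.

Per fold, the pipeline's fitted stages and the model are fit on the training
side only. Stateless per-spectrum stages are computed once on the whole
cohort — they are per-spectrum maps, so this is mathematically identical to
per-fold application and merely avoids recomputing 80 SNIP iterations per
fold. Pooled validation predictions give one confusion matrix (rows = true
class) and a metrics report: per-class precision/recall/F1, accuracy, and
support-weighted averages, kept at full precision with one-decimal rounding
for display. With balanced classes, accuracy equals the mean of the two
recalls exactly on counts; the weighted recall is what the ablation reports
as "recall" (they coincide at exact balance). Per-fold metrics are retained
alongside the pooled ones since "averaging over folds" and "pooling
predictions" differ in general.

The ablation harness evaluates the cumulative ladder raw → +SNIP → +L2 →
+median → +PCA(30) on matched folds and seeds, region-selecting at every
rung for comparability, and reports per-rung accuracy/recall, per-step
deltas, and totals (the telescoping identity total = Σ deltas holds exactly
on stored values). The pipeline comparison harness runs the named presets on
identical folds.

## Grad-CAM

For a trained conv model, the saliency of a spectrum is
`ReLU(Σₖ αₖ Aₖ)` where `Aₖ` are the **post-activation** feature maps of the
last convolutional stage and `αₖ` is the spatial mean of `∂(logit)/∂Aₖ`.
Three choices matter: the gradient target is the pre-sigmoid logit
(saturated sigmoids zero the gradients); the feature maps are taken after
the ReLU — pre-activation maps can encode class evidence with negative sign,
which the closing ReLU of the CAM would silently discard, and empirically
this mistargeting sent saliency to flat spectrum regions in a third of
seeded runs; and the map is linearly interpolated from feature-map length to
the input axis (the pooling stride makes that mapping non-trivial) before
min-max normalization to [0, 1]. All-zero maps are returned unnormalized
with a `degenerate` flag. Cohort-level saliency is the pointwise mean over
spectra, re-normalized, thresholded (default 0.5 of maximum) into contiguous
wavenumber bands. On single-discriminative-band simulations the aggregate
argmax lands within one grid step of the injected band across seeds —
provided the preprocessing in that experiment does not include per-spectrum
normalization, which redistributes a single-band class difference across the
whole spectrum through the changed vector norm.

## Problem sizes and test design

The test suite and the acceptance script run end-to-end at deliberately
compact sizes: the full 442-spectrum cohort on the 3165-point reference axis
for cohort-shape, label-recovery and chance-control experiments; a
2 cm⁻¹-step axis or 6–12-patient cohorts where many model fits are needed
(ablation, sentinel, pipeline comparison); 550-point fingerprint-only grids
for conv-net training experiments. Statistical assertions use bounds sized
to the estimator actually tested (e.g. the maximum of ~3000 near-Gaussian
per-channel deviations is bounded at 5 standard errors, not 3; chance-level
accuracies at ±10 points). The heavy-contamination ablation experiment uses
the full-size cohort because per-step accuracy deltas of a few points need
sub-point sampling granularity to resolve their sign reliably.

## Known limitations

- The numpy network engine is CPU-only and unoptimized beyond BLAS-backed
  convolution-as-matmul; it is sized for hundreds of spectra, not millions.
- Simulated effect sizes are placeholders; absolute accuracies on synthetic
  cohorts say nothing quantitative about clinical performance.
- SNV is population-sd by definition here; other packages divide by n−1.
- Grad-CAM is the only attribution method; tree/linear models expose their
  native importances instead.
- No hyperparameter search, calibration, ensembling, transfer learning or
  data augmentation — all out of scope by design.
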
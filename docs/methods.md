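# Methods

`parkfuse` implements an explainable trimodal classifier for Parkinson's
disease (PD) versus healthy control (HC): three modality-specific deep
feature extractors (spiral handwriting images, multi-sensor vertical
ground-reaction-force gait recordings, sustained-vowel phonation), a
class-conditional distribution-level fusion of their embeddings, a
gradient-boosted classification head, and a from-scratch attribution
suite.  This note records the model, its assumptions, the synthetic study
conditions, the numerical choices, and the limits of what the synthetic
experiments demonstrate.

## Modality pipelines

**Gait.**  Recordings are multi-channel VGRF time series (per-sensor
columns for each foot plus per-foot totals, 100 Hz).  Trials are trimmed
to their active span, cut into non-overlapping 2-s windows (Q = 200
samples), and z-scored per channel with the population SD (ddof = 0);
zero-variance channels map to zeros rather than raising, because flat
sensors occur in real insole data.  Padded final windows are produced by
the segmenter (with an explicit padding mask) but excluded from model
fitting: the masked global average over a short real segment has a larger
sampling variance than a 200-step mean, which turns padded windows into
embedding outliers that hijack the unsupervised clustering.

Windows are encoded by a stack of dilated causal 1-D convolutions
(kernel 3, dilations 1-2-4-8, channels 32-32-64-64, identity residual
shortcuts where the width repeats; receptive field
1 + (k−1)·Σdilations = 57 samples).  The exported embedding is the
global average over unmasked time steps of the last feature map
(64-dimensional).  The stack is trained as an autoencoder with a small
causal temporal decoder.  The decoder consumes the *time-resolved*
feature maps, not the pooled vector: window phase is unrecoverable after
global average pooling, so a pooled-latent decoder can only emit
per-channel constants and would leave the encoder effectively untrained.
The pooled vector remains the embedding used everywhere downstream.

Embeddings are standardized, PCA-reduced (95 % variance retained), and
K-means clustered (k-means++ with 10 restarts); K is chosen by maximum
mean silhouette over K = 2…6, ties toward smaller K.  Standardizing
before PCA keeps a handful of high-variance noise filters from
monopolizing the retained components.  A multinomial softmax head is
trained on the cluster pseudo-labels (full-batch gradient descent on
internally standardized features).  For evaluation, clusters are read as
clinical classes by majority vote of the true labels inside each cluster;
silhouette often selects a K that *refines* the two classes, and the
majority-vote mapping is how a refined partition is scored against the
binary ground truth.

**Speech.**  Audio is resampled to 16 kHz when needed and converted to a
log-Mel spectrogram: hand-framed STFT (25 ms Hann window, 10 ms hop,
frames = 1 + ⌊(T−w)/hop⌋), a triangular filterbank of 64 filters with
unit peaks spaced uniformly on the mel scale
(mel = 2595·log10(1 + f/700)) over 50–8000 Hz, then log(E + b) with
b = 10⁻⁶.  The classifier is a reduced mobile-inverted-bottleneck CNN
("b0-mini": stem conv, three MBConv-style blocks with depthwise 3×3
convolutions and squeeze-excitation, widths 16–32), global average
pooling, and a softmax head; the GAP vector is the exported embedding.
The full-width layout is expressible through `SpeechEncoderSpec`, but the
reduced default is sized for CPU desk-scale training.

**Handwriting.**  Images are converted to grayscale, bilinearly resized
to 224×224, and min–max contrast-normalized to [0, 1] (constant images
map to zeros).  The network input is the *ink intensity* (1 − pixel): a
sparse positive stroke on a zero background conditions the convolutions
far better than a thin dark line on a saturated white field.  The
encoder is a reduced residual CNN (4× average-pool stem, three
downsampling stages of widths 16-32-48, one identity residual block per
stage, GAP head).  Residual branches are zero-initialized at their last
convolution so each block starts as the identity; without this, a deep
stack roughly doubles activation variance per block and training
destabilizes at this data scale.

As an ancillary tremor diagnostic, the stroke can be skeletonized
(morphological thinning), ordered from the innermost point outward by a
nearest-neighbour walk, spline-smoothed, and differentiated to the
signed curvature κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2}.  Curvature is
*not* concatenated into the learned embedding by default
(`append_curvature` switches on (mean, SD, max) of |κ|); the learned
model and the geometric diagnostic are kept separate because nothing in
the architecture requires their fusion.

## Distribution-level fusion and classification

The three cohorts share no subjects, so fused vectors cannot be built
per subject.  Embeddings are pooled per class within each modality and
"pseudo-subjects" are assembled by drawing one embedding per modality
from the matching class pool — without replacement while a pool lasts,
refilled with replacement afterwards — and concatenating
[v_speech ∥ v_hand ∥ v_gait] with recorded index spans.  Per-class,
per-modality population means and SDs of the pooled embeddings are
recorded alongside the sampling recipe.  Speech embeddings are
PCA-reduced first (16 components by default; the basis is fitted on the
training pool only).

Test-time vectors are assembled from the *held-out* pools with labels
used only for class-matched pairing and scoring; no fitted transform
(PCA, standardizer, SMOTE, descriptors) ever sees held-out data, and
fit hashes on the fitted transforms make the train-only provenance
checkable.  A label-permutation control (shuffling training labels
before assembly drives held-out accuracy to chance) guards against the
assembly recipe itself leaking class information.

Fused training vectors are standardized (train statistics applied
unchanged to the test partition), balanced by SMOTE (k = 5 nearest
minority neighbours, interpolation coefficient uniform in [0, 1]), and
classified by gradient-boosted trees (XGBoost: 300 trees, depth 4,
learning rate 0.1, λ = 1, γ = 0 — conservative defaults).  The per-tree
complexity penalty is Ω = γM + ½λ‖w‖².  SHAP-guided feature selection
ranks fused features by mean |Shapley value| on training vectors and
keeps the top 90 %; the main head is retrained on the kept features,
and the "without XAI selection" ablation row uses the full-feature head.
Soft voting (averaging the three per-modality class-probability heads)
is available as an alternative ensemble mode; boosted trees on the
concatenation are the default final head.

Two split conventions exist in practice (a single 60/40 split versus
70/15/15 subject-wise partitions); both are exposed, and the harness
defaults to subject-wise stratified 5-fold cross-validation applied
identically to every configuration.

## Attribution

All four primitives are implemented from first principles:

* **Exact Shapley values** by full subset enumeration (≤ 15 features),
  with the efficiency gap reported; the axioms (efficiency, symmetry,
  dummy, additivity) are asserted on constructed games.
* **Sampled Shapley** by the unbiased permutation estimator with a
  Monte-Carlo standard error per feature; efficiency holds per sampled
  permutation by construction.  For the boosted-tree head the value
  function is the marginal expectation over a seeded training-sample
  background (default 50 rows).
* **Integrated Gradients**: midpoint-Riemann approximation of the path
  integral from a baseline (zeros in standardized feature space; black
  image / silence for raw modalities), 64 steps by default, completeness
  residual reported.
* **Grad-CAM**: α_k = spatial mean of ∂score/∂A_k, L = ReLU(Σ α_k A_k),
  bilinearly upsampled to the input size.  The target layer defaults to
  the last spatial stage and is configurable; the localization check
  uses a finer-resolution variant of the encoder (2× stem pool) because
  a 7×7 final map is too coarse to score overlap meaningfully.

Modality-level importance is Σ|φ| over each modality's span, normalized
to shares.  Cross-fold consistency is the Spearman rank correlation of
per-feature mean |φ| between folds (identical — including constant —
profiles score 1; a constant against a varying profile scores 0).

## Synthetic study conditions

The generators emulate the statistical structure the pipelines consume,
not biomechanics:

* **Spirals** — Archimedean trace r = bθ (4 turns, b = 4 px/radian,
  224² canvas) rasterized with an anti-aliased ~2 px stroke; PD adds a
  radial tremor sinusoid (easy preset: 5 px at 2 cycles/radian, versus
  0.4 px for HC) plus smoothed Gaussian stroke jitter.  The tremor can
  be confined to a polar-angle arc, with a ground-truth pixel mask
  recorded for localization scoring.  Images are pre-quantized to 8-bit
  so the PNG round trip is exact.
* **Gait** — two Gaussian bumps (heel-strike, toe-off) per stride per
  sensor, 8 sensors per foot with heel→toe weighting, both feet sharing
  one stride-time sequence with the right foot phase-shifted by half a
  stride.  `lr_asymmetry` offsets the left/right peak-force ratio *and*
  shortens the weaker side's stance (reduced push-off) — the temporal
  component keeps the class contrast visible after per-channel
  amplitude normalization.  The easy preset gives PD shorter strides
  (1.0 s vs 1.15 s), higher stride-time variability (CV 0.15 vs 0.03)
  and larger asymmetry (0.25 vs 0.02); recordings are padded with rest
  at both ends so every bump decays inside the trace (this is what makes
  the zero-asymmetry case exactly symmetric).
* **Voice** — a formant-shaped harmonic stack (1/h² glottal roll-off
  with Gaussian formant emphasis near 700 and 1220 Hz), equivalent to a
  glottal pulse train through a fixed spectral envelope.  The period is
  redrawn every cycle (jitter, fraction of 1/f0), the cycle amplitude
  perturbed (shimmer), and white noise added at a target SNR; exact
  per-cycle periods are stored as jitter ground truth.  Easy preset:
  jitter 2 % vs 0.2 %, shimmer 8 % vs 1 %, SNR 15 vs 28 dB.

Cohorts are independent per modality with disjoint subject ids; each
subject's class-contrast parameter is spread by U[0.85, 1.15] so
subjects are not clones; all per-subject seeds derive from one master
seed through `numpy.random.SeedSequence`.  The defaults are deliberately
*easily separable* so end-to-end checks exercise pipeline correctness
rather than classifier power; `hard=True` shrinks every contrast to
about a third for power studies.  Scale defaults: the test suite runs
15 subjects per class per modality with reduced encoder epochs
(8/10/12); the acceptance script runs 18 per class with the standard
epochs — sizes chosen as the smallest at which the cross-validated
estimates are stable.

What passing on these conditions does **not** show: robustness to the
heterogeneity of real cohorts (device variation, comorbidity, language
and accent in speech, free-form drawing styles), to label noise, or to
class contrasts near the decision boundary.  Real-data performance
claims require the external corpora this package deliberately does not
bundle.

## Numerical choices and degenerate inputs

* All neural components run in a small pure-NumPy layer engine
  (float64, single-threaded); seeds drive initialization and batch
  shuffling, so training is bit-reproducible per seed.
* Adam (β = 0.9/0.999, ε = 10⁻⁸) everywhere; divergence (non-finite
  loss) raises naming the epoch.
* Silhouette selection rejects candidate K whose clustering collapses
  to one cluster; identical embeddings raise a degenerate-clustering
  error.
* Wilcoxon signed-rank: exact null for n ≤ 25 without zero differences,
  normal approximation otherwise; all-zero differences report p = 1
  with a warning.
* Bootstrap CIs are percentile intervals over 1000 test-set resamples;
  resamples that lose a class are skipped for threshold-based metrics.
* SMOTE refuses a minority class smaller than k + 1 and suggests a
  smaller k.
* Curvature is masked (NaN) where the parametric speed falls below
  10⁻⁹; traces shorter than 5 points are rejected.

## Known limitations

* The reduced encoders are far smaller than production image/audio
  backbones; their capacity suffices for the synthetic contrasts only.
* Grad-CAM localization is evaluated at 14×14 resolution; finer
  localization claims would need higher-resolution feature maps.
* The distribution-level fusion assumes class-conditional independence
  across modalities (true of the synthetic cohorts by construction,
  an approximation for any real population).
* Pseudo-label clustering assumes the class contrast dominates the
  embedding geometry; under the `hard` preset silhouette model selection
  can latch onto other structure.
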
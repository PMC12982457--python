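# parkfuse

Explainable trimodal detection of Parkinson's disease (PD) from three
independent digital biomarkers: spiral-tracing images (tremor,
micrographia), multi-sensor vertical ground-reaction-force gait
recordings (stride asymmetry and variability), and sustained-vowel
phonation (jitter, shimmer, spectral instability).  It is aimed at
researchers who want a tested, fully inspectable reference
implementation of early feature fusion across heterogeneous biomarker
cohorts — including the common situation where the three datasets share
**no subjects** — with attribution methods built in rather than bolted
on.

## The model

Each modality has a dedicated deep feature extractor:

* **gait** — 2-s VGRF windows, z-scored per channel
  (v_norm = (q − mean)/SD), encoded by stacked dilated causal temporal
  convolutions with residual shortcuts; the embedding is the global
  average f = (1/Q) Σ_t h_t of the last feature map.  The encoder is
  trained as an autoencoder; embeddings are PCA + K-means clustered
  (K by maximum silhouette s = (c − d)/max(c, d)) and a softmax head is
  trained on the cluster pseudo-labels.
* **speech** — log-Mel spectrograms (STFT → triangular filters on
  mel = 2595·log₁₀(1 + f/700) → log(E + b)) classified by a reduced
  depthwise-separable CNN with squeeze-excitation ("b0-mini") and a GAP
  head.
* **handwriting** — 224×224 contrast-normalized spiral images through a
  reduced residual CNN (r = F(x) + x blocks, GAP head); stroke
  curvature κ = (x′y″ − y′x″)/(x′²+y′²)^{3/2} is available as an
  ancillary tremor diagnostic.

Because the cohorts are disjoint, fusion happens at the
feature-distribution level: embeddings are pooled per class, and
trimodal "pseudo-subjects" v_fused = [v_speech ∥ v_hand ∥ v_gait] are
assembled by class-matched sampling (train and test pools kept strictly
separate).  Fused vectors are standardized, SMOTE-balanced, pruned by
mean-|SHAP| feature selection, and classified by gradient-boosted trees
(objective Σ E(h, ĥ) + Σ Ω, Ω = γM + ½λ‖w‖²).  Attribution is computed
from first principles: exact/permutation-sampled Shapley values,
Integrated Gradients (IG_i = (k_i − k′_i)·∫₀¹ ∂f/∂k_i dv), and Grad-CAM
(L = ReLU(Σ_k α_k A^k)), aggregated into per-modality importance shares.

Everything runs on synthetic cohorts whose generators expose the class
structure the pipelines assume (tremor amplitude, gait asymmetry and
stride-time variability, vocal jitter/shimmer/noise) with ground truth
recorded for oracle checks; see `docs/methods.md`.

## Worked example

```python
from parkfuse import TrimodalPDModel

model = TrimodalPDModel.from_synthetic(n_per_class=15, seed=0,
                                       encoder_epochs=(8, 10, 10))
results = model.fit(seed=0)
print(results.summary())
```

takes a few minutes on one CPU and prints:

```
Trimodal Parkinson's disease detection — cross-validated results
==================================================================
folds: 5   seed: 0   ensemble: xgboost

                    accuracy  macro_f1    auc     ap  hc_precision  hc_recall  hc_f1  pd_precision  pd_recall  pd_f1  accuracy_sd
handwriting            1.000     1.000  1.000  1.000         1.000      1.000  1.000         1.000      1.000  1.000        0.000
gait                   0.967     0.967  1.000  1.000         1.000      0.933  0.966         0.938      1.000  0.968        0.067
speech                 1.000     1.000  1.000  1.000         1.000      1.000  1.000         1.000      1.000  1.000        0.000
trimodal_no_xai        1.000     1.000  1.000  1.000         1.000      1.000  1.000         1.000      1.000  1.000        0.000
trimodal               1.000     1.000  1.000  1.000         1.000      1.000  1.000         1.000      1.000  1.000        0.000
handwriting+gait       1.000     1.000  1.000  1.000         1.000      1.000  1.000         1.000      1.000  1.000        0.000
handwriting+speech     1.000     1.000  1.000  1.000         1.000      1.000  1.000         1.000      1.000  1.000        0.000
gait+speech            0.967     0.967  0.967  0.967         0.938      1.000  0.968         1.000      0.933  0.966        0.067

trimodal accuracy 1.000 (95% bootstrap CI 1.000-1.000, 1000 resamples)
modality importance (mean |SHAP| share): speech=1.00, handwriting=0.00, gait=0.00
cross-fold attribution rank-correlation: mean 1.00, min 1.00
```

Rows are subject-wise stratified 5-fold cross-validation accuracies for
each modality configuration (the three unimodal encoders, the three
leave-one-modality-out bimodal fusions, and the trimodal head with and
without SHAP-guided feature selection).  On the default easy synthetic
preset every contrast is deliberately well separated, so the fused model
saturates and the boosted trees concentrate their attribution on the
first modality that perfectly splits the classes (here speech) — the
`hard` preset (`from_synthetic(..., hard=True)`) shrinks the contrasts
for less trivial behaviour.  `results.compare("trimodal", "speech")`
runs a Wilcoxon signed-rank test on the paired fold accuracies, and
`results.ablation_frame()` returns the table as a DataFrame.

A thin CLI covers the shell workflows:

```bash
parkfuse simulate --out cohort/ --n-per-class 24 --seed 0
parkfuse run --n-per-class 15 --seed 0
parkfuse evaluate --n-per-class 15 --seed 0
```

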
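# gbradiomics

Ultrasound radiomics for the preoperative characterisation of gallbladder
polyps: distinguishing **pseudo polyps** (cholesterol polyps, class 0 —
non-neoplastic, benign) from **true polyps** (tubular adenomas, class 1 —
neoplastic, with malignant potential). True polyps warrant cholecystectomy,
but on conventional B-mode ultrasound the two entities often look alike, so
quantitative texture and shape analysis of the lesion region is an
attractive aid for radiologists and for researchers studying gallbladder
lesion imaging.

The package implements the full analysis as a tested, reusable library:

1. **Mask processing** — a hand-drawn closed lesion contour is rasterized
   into a binary lesion mask (pixel-center even-odd rule); within-lesion
   Otsu thresholding yields the high-intensity mask; a rectangular band
   around the lesion serves as the reference region.
2. **Spatial features (72)** — 9 first-order intensity statistics including
   lesion/reference ratios RImean and RImedian; gray-level co-occurrence
   matrix (GLCM) energy, contrast, entropy and homogeneity at pixel offsets
   d = 1..15 (60 features); and three binary-texture features of the
   high-intensity mask: area ratio (AR), center deviation degree (CDD) and
   dispersion degree (DD).
3. **Morphological features (8)** — area, convex area, major/minor axis of
   the moment-matched ellipse, perimeter, orientation, equivalent diameter
   and solidity, all in physical (cm-based) units.
4. **Two-stage feature selection** — univariate screening routed by
   Shapiro–Wilk normality (Welch t-test or Kruskal–Wallis), GLCM
   per-type redundancy reduction, then family-wise median thresholding on
   two screening statistics:

   - Fisher inter–intraclass variance ratio
     `Fv = |x̄₀ − x̄₁| / √(σ₀² + σ₁²)`
   - pooled z-score separation
     `F = |x̄₀ − x̄₁| / SD(pooled sample)`

   A feature survives stage 2 iff, within its family (spatial or
   morphological), `Fv ≥ median(Fv)` **and** `F ≥ median(F)` (inclusive).
5. **SVM classification** — stratified 6:4 train/test split, features
   standardized on the training set, RBF-kernel SVM with 5-fold
   cross-validated hyperparameters; reported metrics are accuracy,
   sensitivity, specificity, Youden index `Yi = Sen + Spc − 1`, and the
   decision-score AUC, for three feature subsets (all selected /
   morphological only / spatial only).

Because the clinical images are not publicly available, the package ships a
**synthetic cohort generator** that emulates the study population (58
cholesterol polyps vs 41 adenomas by default): speckled, log-compressed
B-mode-like lesions in which class 0 is smaller, more regular, and carries
centrally clustered punctate hyperechoic foci (the cholesterol-crystal
proxy), while class 1 is larger, more irregular and texturally homogeneous.
Every downstream stage is tested against this generator and against
closed-form oracles.

## Worked example

```python
from gbradiomics import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortConfig(n0=100, n1=100, seed=7),
    seed=7,
)
result = run_pipeline(config)
print(result.classification_report.round(3).to_string(index=False))
```

prints

```
              Features   Acc   Sen   Spc    Yi   AUC
          All features 0.925 0.975 0.875 0.850 0.981
Morphological features 0.662 0.750 0.575 0.325 0.732
      Spatial features 0.938 1.000 0.875 0.875 0.997
```

i.e. on the held-out 40% of this synthetic cohort, the SVM on all selected
features classifies 92.5% of lesions correctly, detecting 97.5% of
cholesterol polyps (sensitivity; class 0 is the positive class) at 87.5%
specificity, with an AUC of 0.981; the spatial texture features alone
outperform the morphological (size/shape) features alone. The `examples/`
directory walks through each capability separately (cohort simulation,
feature extraction, selection replay, full pipeline).

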
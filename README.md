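# dermoscan

Automated analysis of dermoscopic skin-lesion images: pre-processing,
lesion segmentation, texture/shape feature extraction, and benign/malignant
classification — with a synthetic-image generator that provides exact ground
truth, so the whole pipeline is testable without any external dataset.

It is aimed at researchers and students working on classical (non-deep)
computer-aided melanoma screening: every stage is an ordinary Python function
over numpy arrays, individually callable, configurable, and covered by
oracle-based tests.

## The pipeline

1. **Pre-processing** — DullRazor-style hair removal (grayscale closing with
   line structuring elements at 0°/45°/90°/135°), grayscale conversion,
   percentile contrast stretch, and a median → Gaussian → Lee smoothing bank.
2. **Segmentation** — two classical procedures, comparable on the same image:
   * *adaptive snake* (AS): an active contour contracted from a rectangular
     initial mask by a balloon force, regularised by boundary smoothing and
     pinned by the image-gradient stopping function
     `g = 1/sqrt(1 + α|∇(G_σ * I)|)`;
   * *region growing* (RG): breadth-first flood from a seed, accepting
     neighbours with `|I(x) − mean(region)| ≤ τ`, then morphological
     opening/closing, largest-component selection and hole filling.
   Masks are scored by pixel accuracy `(TP+TN)/total`, Dice and Jaccard.
3. **Features** — 26 descriptors per lesion: the 20 standard second-order
   GLCM texture statistics (Haralick/Soh/Clausi definitions, 8 gray levels,
   averaged over the four standard offsets) and the ABCD-rule descriptors

   * asymmetry index `ASI = 100·ΔA_K / A_L` (fold across the principal axes),
   * border irregularity `I = (ab / 2π(a²+b²)) · (P²/A)`,
   * HSV colour variance, lesion area `A`,
   * diameter `= sqrt(4A/π)`, and roundness `= sqrt(4πA/P²)`.
4. **Classification** — a small feed-forward network (one hidden layer of 16
   logistic units) and an RBF-kernel SVM on standardized features, with a
   stratified 80/20 train/test split.
5. **Evaluation** — confusion matrix and seven metrics: accuracy,
   sensitivity, specificity, precision, F1 (= Dice), Jaccard `= F1/(2−F1)`,
   and the Matthews correlation coefficient — plus an inversion utility that
   recovers the minimal integer confusion matrix consistent with printed
   percentage metrics.

## Worked example

```bash
python examples/02_preprocess_and_segment.py
```

```
adaptive snake : pixel accuracy 0.9986, Dice 0.9907, Jaccard 0.9816
region growing : pixel accuracy 0.9901, Dice 0.9311, Jaccard 0.8712
snake converged: True after 100 iterations
```

A hairy synthetic lesion is cleaned and segmented by both methods and scored
against the exact ground-truth mask.  The snake settles on the gradient ridge
of the fuzzy lesion border (accuracy 99.9%), while region growing stops where
the intensity leaves its tolerance band, slightly under-segmenting the soft
border (99.0%) — the same ranking direction the two methods show on real
dermoscopy.  The other examples cover dataset synthesis (`01`), feature
extraction (`03`), end-to-end classification (`04`) and the printed-metric
inversion (`05`).

The same functionality is exposed as a CLI:

```bash
dermoscan synth --n-benign 80 --n-malignant 40 --out data --seed 0
dermoscan run --manifest data/manifest.csv --out results --method as --classifier ann
dermoscan verify-published-metrics
```

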
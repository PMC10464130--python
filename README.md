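# radscar

Radon-descriptor texture analysis for distinguishing **left-ventricular
endocardial scar tissue** from **normal myocardium** in cardiac CT.

Scar tissue after myocardial infarction retains contrast agent in
delayed-enhancement CT and appears hyperintense relative to the healthy
wall (pixel values in Hounsfield units, HU). `radscar` is aimed at
medical-image-analysis researchers who want a reproducible, fully tested
implementation of the classical descriptor chain for this problem:

1. **Scar-candidate localization** — a myocardium pixel is a candidate
   when its value exceeds μ + k·σ of the healthy wall (k = 3 by
   default), followed by binary opening/closing cleanup;
2. **Patch extraction** — 25 × 25 tiles fully inside one class region;
3. **Radon transform** — each tile is projected over θ = 0°…179°,
   giving a sinogram R(t, θ) = Σ_pixels v·w(t − x·cos θ − y·sin θ);
4. **LBP texture features** — the rotation-invariant uniform local
   binary pattern histogram (P = 8, R = 1) of the rescaled sinogram:
   exactly 10 bins (set-bit counts 0–8 of uniform codes + one
   non-uniform bin);
5. **Class dissimilarity** — the 1-D Wasserstein distance
   W₁(p, q) = Σ_k |CDF_p(k) − CDF_q(k)| between the class-mean
   histograms (range 0–9);
6. **Classification** — decision tree, RBF SVM and logistic regression
   under stratified 5-fold cross-validation, reporting sensitivity,
   specificity and accuracy with scar as the positive class.

Because clinical delayed-enhancement CT datasets are rarely shareable,
the package ships a **phantom generator**: annular "myocardium" at
59 ± 21 HU with scar arcs at μ + 4σ whose noise field is spatially
smoothed, giving both the intensity contrast the thresholding rule needs
and a texture contrast for the descriptor — with exact ground-truth
masks. See `docs/methods.md` for the model, conventions, and what the
phantom does and does not emulate.

## Worked example

```python
from radscar import (
    PhantomSpec, generate_phantom, scar_pipeline, dice,
    phantom_patch_sets, run_models,
)
from radscar.features import radon_lbp_features, class_dissimilarity

spec = PhantomSpec(seed=1)                       # 256x256, scar arc 30-90 deg
image, myocardium, scar_truth = generate_phantom(spec)

candidate = scar_pipeline(image, myocardium)     # mean+3*SD rule + cleanup
print("Dice vs truth:", round(dice(candidate, scar_truth), 4))

patches = phantom_patch_sets(spec, 100)          # 100 tiles per class
features = radon_lbp_features(patches)           # 10-bin LBP of Radon images
print("class Wasserstein:", round(class_dissimilarity(features), 3))

for report in run_models(features, k=5, seed=1):
    print(report.model, round(report.accuracy, 3))
```

prints

```
Dice vs truth: 0.9997
class Wasserstein: 0.586
decision_tree 1.0
svm 1.0
logistic_regression 1.0
```

The Dice score says the thresholding + morphology stage recovered the
ground-truth scar arc almost exactly; the Wasserstein value quantifies
how far apart the two classes' mean texture histograms sit on the 0–9
bin axis; and all three classifiers separate the (deliberately
well-separated) phantom classes perfectly under 5-fold cross-validation.
On a null phantom where both classes share one distribution, the same
chain yields accuracies near 0.5 and a Wasserstein distance near 0.

The same run is available from the shell:

```bash
radscar run-all --print-defaults > config.txt   # edit as needed
radscar run-all --config config.txt --out-dir run1
```

which writes every intermediate (phantom images and masks, candidate
mask, patch set, sinograms, feature table, dissimilarity and metrics
JSON) plus a manifest with checksums; re-running a config reproduces
`metrics.json` byte for byte. Individual stages are exposed as
`radscar phantom | localize | patches | radon | features |
dissimilarity | train`.

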
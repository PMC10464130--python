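# Methods

## Problem and pipeline

Infarcted (scarred) left-ventricular myocardium retains contrast agent in
delayed-enhancement cardiac CT and appears hyperintense relative to the
healthy wall. `radscar` implements a texture-descriptor pipeline that
separates endocardial scar tissue from normal myocardium in 2-D
short-axis slices whose pixel values are Hounsfield units (HU):

1. **Localization.** Healthy-wall statistics (mean μ, SD σ) are
   estimated inside the myocardium mask; pixels strictly above
   μ + k·σ are scar candidates (k = 3 by default, the conventional
   delayed-enhancement rule; k = 2 is the more permissive contrast
   rule). Binary opening then closing removes speckle and fills
   pinholes.
2. **Patches.** 25 × 25 tiles are sampled, each lying *entirely* inside
   one class region, so labels are unambiguous.
3. **Radon descriptor.** Each tile is projected over 180 angles
   (0°–179°, 1° steps); the sinogram is rescaled to [0, 255] and treated
   as a grayscale "Radon image".
4. **Texture features.** The rotation-invariant uniform LBP histogram
   (P = 8, R = 1) of the Radon image gives a 10-bin feature vector.
5. **Class dissimilarity.** The 1-D Wasserstein distance between the two
   class-mean histograms, on the ordered bin index with unit ground
   distance (range [0, 9] for 10 bins).
6. **Classification.** Decision tree, RBF SVM, and L2 logistic
   regression under stratified 5-fold cross-validation; confusion counts
   are pooled over folds (micro-average) before computing sensitivity,
   specificity, and accuracy, with scar as the positive class.

## Radon transform: formulation and numerical choices

The projection of a square n × n tile at angle θ assigns each pixel at
(row r, col c) the signed offset

    t = (c − c₀)·cos θ + (r − c₀)·sin θ,   c₀ = (n − 1)/2,

and splits the pixel's value linearly between the two unit-spaced offset
bins bracketing t (1-D bilinear splatting — the adjoint of linear
interpolation along the offset axis). The offset axis spans the tile
diagonal, so no mass leaves the frame. This formulation was chosen over
rotate-the-image-and-sum-columns because its conservation laws are exact
rather than approximate: per-angle mass conservation, projection at 0°
equal to column sums, offset reversal between θ and θ + 180°, and
linearity in the image all hold to machine precision, which makes the
transform testable against a brute-force per-pixel oracle at 1e-6
tolerance. The default angle set is the conventional half circle
(0°–179°, 1° steps); it is configurable, and results are insensitive to
moderate coarsening (the test suite uses 3–4° steps where speed
matters).

## LBP conventions

Bit i of a pixel's 8-bit code is set when its i-th neighbor — counted
counterclockwise from the east neighbor — is **≥** the center; ties set
the bit, so a constant image deterministically codes 255 (label 8). A
code is *uniform* when its circular bit pattern has ≤ 2 transitions;
exactly 58 of the 256 codes are uniform. Uniform codes are keyed by
their set-bit count (labels 0–8) and the rest pool into label 9, giving
exactly ten labels. Codes depend only on the ordering of intensities, so
the feature is invariant under any strictly increasing intensity
transform — in particular under the sinogram's linear rescale, which
means the descriptor responds to *texture*, not to the absolute HU
offset between scar and normal tissue.

## Healthy-wall statistics

`region_stats` reports the plain mean and **population** SD (divisor n;
a single convention, stated once). When the myocardium already contains
scar, the plain statistics are useless for thresholding: with ~17 % of
the wall at μ + 4σ the mixture SD roughly doubles and μ + 3·SD lands
*above* the scar intensity. `robust_healthy_stats` therefore:

1. initializes location at the median and scale at 1.4826 × the
   *left-sided* MAD (deviations below the median) — for any minority of
   bright scar the lower half of the intensity distribution is pure
   healthy tissue, so this scale cannot be inflated (the ordinary
   two-sided MAD fails this at ~30 % scar fraction);
2. iteratively keeps values ≤ mean + 2·SD, refitting plain mean/SD until
   the cutoff stabilizes;
3. refits once over values ≤ mean + 3·SD to undo the shrinkage the tight
   clip causes on scar-free data.

On scar-free phantoms the estimate is within ~2 % of the plain
statistics; with 17–30 % scar it recovers the generative 59/21 HU to
similar precision. `scar_pipeline` uses this estimator when no healthy
statistics are supplied; callers with a known healthy reference region
should pass its `region_stats` explicitly.

## Morphology conventions

Structuring elements are explicit offset sets containing the origin;
shipped defaults are the 4-connected cross and the 3 × 3 square. Erosion
and dilation read out-of-bounds pixels as false, so erosion shrinks
components at the image border. Opening is erosion-then-dilation.
Closing is computed on a false-padded plane and cropped back — i.e. it
is the restriction of the infinite-plane closing to the frame — because
a direct dilate-then-erode under the outside-is-false rule erodes away
true pixels touching the border and would break the extensivity law
x ⊆ close(x). Cleanup order is opening-then-closing by default
(speckle removal before hole filling); the reverse order is exposed.
All thresholds use strict `>`.

Region growing is seeded flood fill: the maximal 4-connected component
of pixels within a fixed tolerance of the *seed* value (not a running
mean) — the simplest deterministic variant.

## The phantom: what it emulates and what it does not

The phantom renders a 256 × 256 slice with an annular myocardium
(radii 60/115 px about the image center) on a 0 HU background:

| parameter | default | meaning |
|---|---|---|
| `myo_mean`, `myo_sd` | 59, 21 HU | healthy wall intensity, i.i.d. Gaussian |
| `scar_arcs` | (30°, 90°) | one arc, ~17 % of the annulus |
| `scar_mean` | μ + 4σ = 143 HU | clears the 3-SD rule with margin |
| `scar_sd` | 21 HU | scar noise SD before smoothing |
| `scar_texture_scale` | 3 px | moving-average window over the scar noise |

Angles are degrees counterclockwise from the positive column axis
(visual CCW), range [0, 360). The scar noise field is generated over the
full grid and smoothed *before* masking, so scar-edge pixels have the
same statistics as the scar interior. Smoothing gives scar spatial
correlation (and a lower point variance) that the i.i.d. healthy wall
lacks; this is the texture contrast the Radon–LBP descriptor detects
once intensity is normalized away. The arc fraction was chosen as a
realistic minority that still leaves well over 100 eligible 25 × 25
origins in each class.

The phantom does **not** emulate: 3-D geometry or cardiac motion, blood
pool or other-organ contrast, CT noise spectra (beam hardening, streak
artifacts), partial-volume effects at tissue boundaries, patient-level
variability, or any validated texture model of real fibrosis — the
smoothed-Gaussian scar texture is a construction of this package. Tests
passing on the phantom therefore demonstrate that the pipeline is
*internally correct and sensitive to a known intensity + texture
contrast*; they are not evidence about classification performance on
clinical CT.

A negative control (`null_patch_sets`) draws both "classes" from the
same healthy distribution of a scar-free phantom; classifiers should sit
at chance (accuracy ≈ 0.5) and the class Wasserstein distance near 0.
This calibrates that the pipeline does not manufacture signal.

## Classifier defaults

Decision tree: unlimited depth, min split 2, min leaf 1, unlimited leaf
nodes, balanced class weights — all overridable through configuration.
SVM: RBF kernel, C = 1, γ = "scale". Logistic regression: L2 penalty,
C = 1. Feature vectors are probability histograms (already on [0, 1]),
so no additional scaling is applied. Fold shuffling and tree tie-breaks
are seeded; a fixed configuration reproduces metrics byte for byte.

## Problem sizes

The shipped study conditions are 100 patches per class per phantom,
180 projection angles, 5 folds; the acceptance script runs one phantom
seed plus one null control (≈ 4 s), and the signal-recovery test repeats
the study over 10 phantom seeds. Unit tests use smaller phantoms
(160–192 px) and coarser angle grids (3–4°), which the package exposes
as ordinary parameters.

## Known limitations

* 2-D only; no patient-level grouping in cross-validation (patches from
  one phantom share a noise field, so patch-level folds are optimistic
  relative to subject-level splits on real data).
* The mapping from the descriptor's 10 bins to physical scar
  architecture is not modeled; the feature is a generic texture
  statistic.
* Raster dialects store HU as integers (offset +1024); sub-HU precision
  requires the csv-matrix dialect.
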
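# Methods

This note documents the models, the pinned numerical choices, and what
the synthetic data can and cannot establish. It is the package's own
account of its science; every number mentioned here is computed by the
test suite or by `scripts/acceptance.py` at run time.

## Problem setting

Three seed classes — genuine spine-date seed (ZSS) and the market
substitutes ZMS and HAS — are photographed one seed per frame on a
contrasting dark background. The pipeline reduces each photograph to
features, fuses them into two scalars (fire, ice), and asks whether the
fused representation discriminates the classes as well as the full
feature set.

## Segmentation

The seed mask is Otsu's threshold on the Rec.601 luma
(0.299 R + 0.587 G + 0.114 B). The threshold is the exhaustive argmax
over t ∈ {0..255} of the between-class variance ω₀ω₁(μ₀−μ₁)², ties
broken toward the smallest t, pixels strictly above t forming the
bright class. The bright class is taken as the seed (staging is
bright-on-dark); the raw binary image is cleaned by keeping the largest
8-connected component and filling its holes, so each sample contributes
exactly one solid region. Degenerate (constant) images raise an error
rather than returning an arbitrary mask. Imaging geometry is otherwise
unconstrained: no color calibration or shadow handling is attempted.

## Color features

Nine channel means over the foreground (plus SDs as auxiliary columns):
R, G, B (0–255); L\* (0–100), a\*, b\* (signed) under sRGB decoding
with the 0.04045 linearization threshold, D65 white and the 2°
observer (delegated to scikit-image's `rgb2lab`); and HSI with
I = (R+G+B)/3 on the 0–255 scale, S = 1 − 3·min(R,G,B)/(R+G+B), and H
in degrees from the arccos formula with H := 360° − θ when B > G.
Conventions pinned to avoid NaN: S := 0 for black, H := 0 whenever
S = 0. The hue mean is circular (resultant of unit vectors) and its SD
is the circular SD √(−2 ln R̄); an arithmetic hue mean would be
meaningless near the 0/360 wrap. All SDs are population (divide-by-n)
SDs — over thousands of foreground pixels the distinction from the
sample SD is negligible, but one convention must be fixed. The
chemometrics stage uses the 9 means only; SDs are exported but excluded
by default.

## Texture features

**GLCM.** Gray values are quantized uniformly to 32 levels
(⌊g·32/256⌋); pair counts at distance 1 are accumulated only where both
endpoints lie in the mask, symmetrized, normalized, and features are
averaged over the four directions 0°, 45°, 90°, 135° (a set closed
under 90° rotation, making the averaged features rotation-invariant).
The six statistics are contrast ΣP(i−j)², dissimilarity ΣP|i−j|,
homogeneity ΣP/(1+|i−j|) (the inverse-difference form; the literature
also uses 1+(i−j)², so the choice is declared), ASM = ΣP², energy =
√ASM, and correlation, defined as 1 for a zero-variance (single-level)
matrix: constant texture is perfectly self-correlated and the
convention keeps feature tables NaN-free. Quantization level, distance
and angle aggregation are pinned here because small foregrounds make 32
levels a robust standard; GLCM entropy is deliberately not computed.

**Law's energies.** The 16 kernels are outer products of
L5 = [1,4,6,4,1], E5 = [−1,−2,0,2,1], S5 = [−1,0,2,0,−1] and
R5 = [1,−4,6,−4,1], named row-vector-first (L5E5 = L5ᵀ·E5). The "R"
vector is the standard ripple filter; no alternative 5-tap vector
exists for the occasionally seen "reflection" gloss. The protocol is
classical: subtract the 15×15 local mean (illumination removal),
convolve separably with reflect padding, take |response|, smooth with a
15×15 moving average, and average the energy map over the mask eroded
by 7 px so window support never leaves the seed. A constant image gives
exactly zero energies, and any DC offset leaves the features unchanged.

## Fire–ice fusion

The fusion collapses 31 features to 2 without batch statistics, so a
single image has well-defined values.

* **Fire.** Each pixel's nine channels are normalized to [0, 1] by
  their natural ranges (R, G, B, I by /255; L\* by /100; a\*, b\* by
  (v+128)/255; H by /360; S as is) and averaged with uniform weights
  (a weights vector is accepted for sensitivity analyses). The map is
  monotone in brightness, consistent with the documented fire ordering
  HAS > ZSS > ZMS tracking the brightness ordering. The *fire
  foreground* is the cleaned Otsu binarization of this map scaled to
  0–255; the fire value is the map's mean over that foreground.
* **Ice.** The 22 texture categories are brought onto [0, 1] —
  contrast/(L−1)², dissimilarity/(L−1), homogeneity, energy, ASM,
  (correlation+1)/2 — and the unbounded Law's energies are
  self-normalized as e/(e + e_L5L5 + ε), ε = 10⁻¹², then averaged.
  Each kernel's energy is measured against the luminance energy of the
  same image, so the ratio is ≈0.5 for strongly textured regions and 0
  for flat ones; L5L5's own ratio is retained so the 22-category
  accounting stays intact. A constant region gives ice = 4/22 exactly.
  The *ice score map* used for the ice foreground chart is the min–max
  rescaled sum of the 15 zero-sum-kernel energy maps; L5L5 is excluded
  there because it is a luminance, not a texture, channel.

The unweighted means are the minimal-assumption fusion: the original
fusion weights are not published, and a uniform mean is monotone,
reproducible and replaceable via configuration.

## Chemometrics

PCA operates on the autoscaled (mean-centered, unit-variance) table via
the SVD; explained percentages come from squared singular values and
sum to 100 over all min(n−1, p) components. Autoscaling refuses
zero-variance columns by name rather than silently dropping them.

PLS-DA regresses the centered one-hot class matrix on the autoscaled
features (NIPALS PLS2 with deflation; unit-norm weight vectors); class
prediction is the argmax of predicted dummy scores. R²Y is the fitted
fraction of label variance; Q² is 1 − PRESS/SS under stratified 7-fold
cross-validation (the fold count follows the default of the
chemometrics software this workflow emulates, and falls back to the
smallest class size when classes are smaller), with per-fold
re-estimation of the scaling so no test information leaks. UV (unit
variance) scaling is used throughout; Pareto scaling is not offered.
VIPⱼ = √(p Σₐ SSYₐ wₐⱼ² / Σₐ SSYₐ) with SSYₐ = ‖tₐ‖²‖qₐ‖², so
Σ VIP² = p identically. The permutation test refits the model on
shuffled labels (200 rounds by default) and reports the scatter of
(label correlation, R²Y, Q²) plus the empirical
p = (#{permuted Q² ≥ original Q²} + 1)/(nperm + 1); the smallest
achievable p at 200 permutations is 1/201 ≈ 0.005. The marker rule is
strict: VIP > 1 and one-way ANOVA p < 0.05. The p-values come from a
per-feature F-test; post-hoc letter displays (Duncan's multiple range
test) are out of scope because the selection rule only consumes a
per-feature p. Default component counts: 3 on the raw table, 2 on the
2-variable fused table.

## Classifier validation

A deterministic per-class 70/30 split (train count = round(0.7·n) per
class, seeded shuffle) feeds four families with pinned defaults: BP —
one hidden layer of 16 units (MLP, backpropagation); SVM — RBF kernel;
RF — 500 trees; DBN — Bernoulli RBMs of 64 and 32 hidden units
pretrained by contrastive divergence on min–max scaled features, whose
weights initialize a logistic-activation MLP fine-tuned end to end
under a softmax output (L-BFGS). Fine-tuning the whole stack is the
standard DBN recipe; a softmax trained on frozen RBM features alone is
not used because with very few visible units the unsupervised
pretraining leaves near-zero weights and the frozen representation
collapses classes. BP/SVM/RF standardize features with training-split
statistics only. None of the hyperparameters are searched per dataset.

## Synthetic data: what it emulates and what it does not

Each rendered sample is a rotated filled ellipse (radii drawn from
55–90 px on a 256×256 canvas) on a dark field (30 ± 5), colored at a
class base L\*a\*b\*, with additive noise, optional salt speckle
(pixels set to 255), an optional coarse mottle (gaussian-blurred noise,
σ = 2 px) and a ±8% vertical shading ramp. Class defaults:

| class    | L\*, a\*, b\* | noise SD | smoothing | speckle | mottle SD |
|----------|---------------|----------|-----------|---------|-----------|
| synthHAS | 65, 18, 30    | 4        | 3 px      | 0       | 0         |
| synthZSS | 48, 25, 22    | 6        | none      | 0.02    | 0         |
| synthZMS | 38, 32, 35    | 18       | none      | 0       | 10        |

"Smoothing" is a uniform mean filter applied to the noise field (size
1 = white noise). The defaults are tuned — and tested at master seeds
42, 43 and 44 — to reproduce the documented ordinal structure:
L\* HAS > ZSS > ZMS; a\*, b\* highest in ZMS; GLCM contrast highest in
ZSS; homogeneity and energy highest in HAS; all 16 Law's energies
highest in ZMS.

One design constraint is worth recording. For spatially uncorrelated
texture, the distance-1 GLCM contrast equals the pixel variance divided
by the squared bin width times two — whatever mixture of noise and salt
produces that variance — while the Law's energies are mean-absolute
statistics of the same variance. A class can therefore top the contrast
ranking without topping the energy ranking only if its variance is
concentrated in sparse large jumps (which quadratic statistics weight
fully and mean-absolute statistics discount) or if spatial correlation
separates the two scales. The defaults use both levers: ZSS's variance
comes from sparse bright speckle over mild noise, and ZMS adds a
low-frequency mottle that feeds the L5 luminance band without adding
neighbor contrast.

The generator emulates class-conditional color and texture statistics
only. It does not model seed shape differences, lighting or
white-balance drift, specular geometry, focus blur, multi-seed frames,
or the biological microstructure of the testa. Consequently, passing
tests demonstrate that the *pipeline* — features, fusion, chemometrics,
classifiers — behaves correctly and reproduces the ordinal structure it
was pointed at; they do not certify the accuracy figures attainable on
real photographs, and the package makes no numeric claims about the
real 488-batch survey beyond the dimensional accounting
(488 × 9 = 4392 and 488 × 22 = 10736 feature values).

At the default study size (30 seeds per class) the classes are, by
construction, cleanly separated: all four classifiers typically reach
100% on both tables, so the fused-vs-raw comparison shows "no accuracy
lost", not "accuracy gained". The acceptance script reports the
fused-table accuracy range and the mean delta so this is visible rather
than implied.

## Numerical conventions and degenerate inputs

* Otsu on a constant image, a mask with no valid pixel pair, an
  eroded-to-empty mask, and a flat texture-energy map all raise
  `DegenerateInputError`; batch reducers skip such samples with a
  logged warning instead of aborting the run.
* Correlation of a single-level GLCM is 1; hue of an achromatic pixel
  is 0; saturation of black is 0.
* ε = 10⁻¹² guards the Law's ratios against 0/0 on flat regions.
* All stochastic steps (rendering, splits, permutations, model
  initialization) take explicit seeds; per-image seeds derive from the
  master seed, so datasets are bit-reproducible.
* Problem sizes in tests and the acceptance script (30 per class for
  the study conditions; 12 per class for the cross-seed ordering
  replicates; the 300/88/100 survey only for counting) are chosen to
  keep the full run comfortably fast while leaving every ordering with
  a clear margin.

## Known limitations

* The fusion weights are uniform by design; if the original weighted
  fusion differed, absolute fire/ice values would shift (orderings
  driven by brightness would not).
* The ice value mixes quantization-dependent terms (contrast,
  dissimilarity) with quantization-free ones; changing the GLCM level
  count rescales two of the 22 terms.
* Q² uses deterministic (unshuffled) stratified folds; with strongly
  ordered inputs this is conservative but reproducible.
* The polarity rule in segmentation assumes the seed is the brighter
  Otsu class; dark seeds on a bright field would require inverting the
  staging assumption.
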
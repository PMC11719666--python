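# seedvision

Machine-vision authentication of spine-date seed — *Ziziphi Spinosae
Semen* (ZSS), a widely used and increasingly adulterated medicinal and
food seed — against its two common market counterfeits, *Ziziphi
Mauritianae Semen* (ZMS) and *Hovenia Acerba Semen* (HAS).

The package implements the full desk pipeline for telling the three
classes apart from ordinary RGB photographs of single seeds:

1. **Color features** — foreground means (and SDs) of the nine
   chromaticity channels R, G, B, L\*, a\*, b\*, H, S, I across the
   RGB, CIELAB (sRGB decoding, D65, 2°) and HSI color spaces, over an
   Otsu-segmented seed mask.
2. **Texture features** — the 22 texture categories: six gray-level
   co-occurrence matrix statistics (contrast, dissimilarity,
   homogeneity, energy, correlation, ASM; 32 gray levels, distance 1,
   averaged over 0°/45°/90°/135°) and the sixteen Law's texture
   energies (mean |response| to the 5×5 kernels built from
   L5/E5/S5/R5, after 15×15 local mean removal).
3. **Fire–ice fusion** — the dimensionality-reduction step at the core
   of the workflow. Per sample,

   * fire = mean over the Otsu *fire foreground* of the per-pixel score
     (1/9) Σ<sub>c</sub> x̃<sub>c</sub>, where x̃<sub>c</sub> is each of
     the nine channels normalized to [0, 1] by its natural range;
   * ice = (1/22) [ contrast/(L−1)² + dissimilarity/(L−1) + homogeneity
     + energy + ASM + (correlation+1)/2 + Σ<sub>k=1..16</sub>
     e<sub>k</sub>/(e<sub>k</sub> + e<sub>L5L5</sub> + ε) ],

   giving two bounded scalars per seed in place of 31 features.
4. **Chemometrics** — PCA; PLS-DA (NIPALS) against one-hot class
   labels with R²Y, stratified 7-fold Q², a 200-round label-permutation
   test, VIP scores (Σ VIP² = p), per-feature one-way ANOVA, and the
   marker rule VIP > 1 ∧ p < 0.05.
5. **Reverse validation** — stratified 70/30 split and four classifier
   families (BP neural network, RBF-SVM, a DBN with RBM pretraining and
   backprop fine-tuning, 500-tree random forest) on the raw versus the
   fused table, with accuracies and confusion matrices.

Because no seed photographs are publicly deposited, the package ships a
**synthetic seed-image generator** (`seedvision.synthseed`) whose three
classes are tuned to reproduce the documented *ordinal* structure of
the real material — brightness HAS > ZSS > ZMS, chroma highest in ZMS,
GLCM contrast highest in ZSS, homogeneity/energy highest in HAS, all 16
Law's energies highest in ZMS — so every stage runs and is testable end
to end. See `docs/methods.md` for what this does and does not show
about real photographs.

## Worked example

```sh
python examples/03_fire_ice_fusion.py
```

```
   sample_id    label   fire    ice
synthHAS-001 synthHAS 0.5092 0.1885
synthHAS-002 synthHAS 0.5101 0.1885
synthHAS-003 synthHAS 0.5105 0.1904

            fire             ice
            mean     std    mean     std
label
synthHAS  0.5101  0.0011  0.1889  0.0013
synthZMS  0.4001  0.0007  0.2004  0.0013
synthZSS  0.4244  0.0009  0.2495  0.0014

fire ordering: synthHAS > synthZSS > synthZMS
```

Each row is one seed image reduced to its two fused scalars. The fire
means follow the brightness ordering of the three species (HAS
brightest, ZMS darkest), the ice means separate the rough-textured
classes from the smooth HAS coat, and the within-class SDs are an order
of magnitude smaller than the class gaps — which is why two numbers
suffice for classification. Running
`python examples/04_chemometrics_markers.py` on the same data prints

```
PCA explained %: PC1 73.0, PC2 27.0, cumulative 100.0
PLS-DA: R2Y 0.9969, Q2 0.9967 (7-fold stratified CV), permutation p 0.0050
  fire: VIP 1.0000, ANOVA p 8.32e-150 -> selected
  ice: VIP 1.0000, ANOVA p 1.57e-103 -> not selected
```

i.e. the 2-component PCA of a 2-feature table necessarily explains
100.0% of the variance, the permutation p-value is the smallest
achievable with 200 permutations (no permuted model beats the real
one), and the fire value is the scalar that passes the VIP > 1, p <
0.05 marker rule — the fused color channel carries the discrimination.

The other examples cover rendering/segmentation (`01`), the 31-feature
table and its class orderings (`02`) and the four-model reverse
validation (`05`). A thin CLI wraps the same library calls:

```sh
seedvision all --n-per-class 30 --seed 42 --out runs/demo
```

runs simulate → extract → fireice → analyze → classify and writes the
feature CSVs, chemometrics outputs, per-model JSON reports and a
`summary.json`.

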
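# Methods

## Problem and model

The package classifies 110 × 110 px tiles of Gomori trichrome-stained
muscle images into three classes — `waste` (artifacts or predominantly
connective tissue), `not_ragged` (healthy fiber mosaic), `ragged` (fiber
with a red subsarcolemmal rim) — using hand-crafted features and a
two-stage binary cascade rather than a single three-class model. The
cascade mirrors how a pathologist works: first decide whether a field is
analyzable tissue at all, then look for the disease hallmark within it.
Stage-level positive classes are the classes of interest (`tissue` for
stage 1, `ragged` for stage 2); this affects the labeling of SEN/SPE-style
metrics, not AUC.

## Tiling

Tiles are cut on a 0-based, row-major grid anchored at the image's
top-left corner; tile (r, c) covers the half-open pixel block
[rS, (r+1)S) × [cS, (c+1)S). Residual margins that cannot fill a whole
tile are discarded — for a 1653 × 1239 acquisition and S = 110 this gives
⌊1653/110⌋ × ⌊1239/110⌋ = 15 × 11 = 165 tiles, and it is the only
anchoring consistent with that grid. Images smaller than one tile yield an
empty list with a logged warning, so batch jobs skip degenerate inputs
rather than abort.

## Feature panel

**First-order statistics (13).** Moments are computed on raw values with
population conventions: variance with denominator n, skewness m₃/σ³ and
kurtosis m₄/σ⁴ (no −3 shift). Zero-variance samples define skewness and
kurtosis as 0 so blank tiles stay finite. Energy is the mean of squared
values and RMS its square root. Entropy (base 2, with 0·log 0 ≡ 0) and
uniformity (sum of squared bin probabilities) use an equal-width 32-bin
histogram over the observed [min, max]; a constant sample occupies one bin
(entropy 0, uniformity 1). The 32-bin default matches common radiomics
practice and is exposed in `FeatureConfig`. Moments are deliberately taken
on raw channel values, not on histogram bin centers; only
entropy/uniformity involve the histogram.

**Color (39).** Standard RGB→HSV with hue wrapping on [0, 1) and H = S = 0
for achromatic pixels (scikit-image conventions). First-order panel per
channel.

**Texture (43).** Luminance uses the BT.601 weights 0.299/0.587/0.114
(computed directly; note scikit-image's `rgb2gray` uses BT.709 weights and
would give different values). The tile is quantized to Ng = 32 levels by
equal-width binning of its own range (max value → level Ng; constant image
→ level 1); per-tile min–max quantization keeps texture features invariant
to affine intensity shifts. The GLCM accumulates ordered pairs in both
directions (symmetric matrix), distance δ = 1, and the 21-feature
Haralick-style panel is averaged over the four standard angles; angles
with no valid pixel pair (degenerate shapes) are excluded from the
average. The GLRLM counts maximal runs per angle and averages the
11-feature Galloway panel. The GLSZM labels 8-connected
(Chebyshev-distance-1) equal-level zones with `scipy.ndimage.label`; it is
a single matrix, rotation-independent by construction. Logarithms are base
2 throughout. Degenerate guards: a single-level image has GLCM entropy 0,
energy 1, and correlation defined as 0 when a marginal variance vanishes.
The formula sheet is the set of expressions in `texture.py`; the brute-force
enumeration oracles in the test suite are the normative cross-check.

**Wavelet (52).** One-level separable 2D DWT with the 8-tap
least-asymmetric Daubechies orthonormal pair (`sym4`), periodization
boundary mode. Periodization was chosen because it is the only boundary
convention under which the finite transform is exactly orthonormal:
subband energies sum to the input energy and reconstruction is exact to
round-off, both of which are tested. Exact orthonormality holds for even
dimensions (the 110 px tile path); odd dimensions are padded by one
sample, which keeps reconstruction exact (the subband set records the
input shape and the inverse truncates) but adds redundant energy. Statistics are computed on subband
coefficients (not on back-projected quarter images), one 13-stat panel per
subband. Single-level only; multi-level pyramids are out of scope.

## Feature table and normalization

The 134 feature names (`color.<channel>.<stat>`, `texture.<matrix>.<stat>`,
`wavelet.<subband>.<stat>`) are a stable public contract; extraction
refuses to emit non-finite values. Z-scoring uses per-column mean and
population SD; zero-SD columns map to 0. Normalization is fit on training
rows only — inside each CV fold it is re-fit on the fold's training
portion via the sklearn `Pipeline`, so validation and test rows never
influence the scaling. Fitting on all data would leak split information;
the no-leakage choice is the default and the only supported path.

## Cascade training

Each stage draws its own stratified, seeded 80/20 train/test split
(stage 1 over all tiles with labels collapsed to waste/tissue; stage 2
over ragged/not-ragged tiles only), shared by all three learners of that
stage. Hyperparameters are tuned by random search under stratified
10-fold CV on the training split: the draw with the best mean validation
F1 wins, ties broken by mean accuracy, then by draw order. Search spaces:
random forest — trees 100–1000, features per split 1–134, min leaf 1–10;
gradient boosting (histogram-binned, whose fit cost stays bounded even on
label-free structure) — boosting rounds 50–500, learning rate 0.01–0.3
(log-uniform), depth 1–8; RBF-SVM — C 2⁻⁵–2¹⁵ and kernel width 2⁻¹⁵–2³
(log-uniform), Platt-scaled (sigmoid on 3-fold held-out decision values)
so the cascade gets calibrated probabilities. The tuned
pipelines are refit on the full training split and compared by test-set
AUC; the highest-AUC learner is the stage model. Classes with fewer
members than folds trigger a logged fold-count reduction rather than an
error. Decision threshold is fixed at 0.5 with ≥ mapping to the positive
class.

All seeds (split, folds, search draws, learner internals) derive from one
integer via `numpy.random.SeedSequence`, making selected hyperparameters
and predictions exactly reproducible.

## Evaluation

Confusion matrices use rows = true class, columns = predicted class (the
transposed reading is noted wherever matrices are displayed). The eight
metrics (SEN, SPE, FPR, FNR, PPV, NPV, ACC, F1) follow the standard
formulas; any zero-denominator ratio is reported as 0 with an explicit
degenerate flag so fold-wise batch evaluation never aborts. ROC curves
come from a full threshold sweep (no intermediate-point dropping), sorted
by (FPR, TPR), with trapezoidal AUC; this equals the Mann–Whitney
probability of correct ranking with ties counted ½, which the test suite
verifies against exhaustive pair enumeration.

## Synthetic data generator

The generator emulates the *statistical contrasts* that distinguish the
classes, not their photorealistic appearance: a seeded Voronoi polygon
mosaic with per-fiber HSV jitter and thin dark boundaries (texture and
color structure of muscle tissue); for `ragged`, an annulus of red,
speckled pixels (hue ≈ 0.99, high saturation, salt-noise granules) whose
area fraction lies in the declared range 3–40 % of the tile; for `waste`,
a pale low-saturation background with 1–3 dark elliptical bubbles or fold
streaks. Default class sizes are 250 waste / 100 ragged / 138 not-ragged
(488 tiles). All classes consume an identical random-draw sequence and
differ only in applied amplitudes, so at separation s = 0 the three
generators are byte-identical given the same generator state; s scales
the rim and artifact amplitudes and pulls class base colors toward the
common mixture, so separability rises monotonically with s.

What passing tests show — and do not show: at s = 1 the classes are
linearly well-separated in color space, so test AUC ≥ 0.95 demonstrates
that the feature extractor preserves the class-defining contrasts and
that the training machinery selects and tunes models correctly; it does
not demonstrate clinical performance on real stained tissue, which varies
in staining intensity, focus, and fiber morphology in ways the generator
does not model (no stain variability, no out-of-focus blur, no
photorealistic rim shapes).

## Problem sizes and numerical choices in the shipped checks

The acceptance-style end-to-end checks run the full default dataset (488
tiles) with 10 random-search draws per learner per stage — enough draws
for the search to matter while keeping a full run in the minutes range on
a single CPU. Null-hypothesis runs (permuted labels, separation 0) use 3
draws: a null AUC is insensitive to tuning effort. Reproducibility and
structural tests use smaller tile counts (≈ 50–100) and 5-fold CV for the
same reason; fold counts below the class size are reduced automatically.

## Known limitations

- No whole-slide (pyramidal) input, stain normalization, or overlap
  tiling; acquisition images are assumed already captured at 20×.
- Probabilities of tree ensembles are not calibrated; only the SVM is
  Platt-scaled (needed to get probabilities at all). The 0.5 threshold is
  a convention, not an optimized operating point.
- The three-class problem is only reachable through the two-stage binary
  decomposition; a single multi-class model is out of scope.
- GLCM/GLRLM/GLSZM panel membership follows the standard
  Haralick/Galloway/Thibault feature sets (21/11/11); other radiomics
  families (NGTDM, GLDM) and multi-distance GLCM aggregation are not
  implemented.
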
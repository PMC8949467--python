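# rrfdetect

Automatic recognition of **ragged red fibers (RRFs)** in light-microscopy
images of Gomori trichrome-stained skeletal muscle. RRFs — muscle fibers
with a red, granular subsarcolemmal rim of accumulated abnormal
mitochondria — are a histological hallmark of mitochondrial myopathy, and
screening biopsy images for them by eye is slow and poorly standardized.
`rrfdetect` is a tile-classification pipeline for this task, aimed at
neuromuscular-pathology and biomedical image-analysis groups.

## Method

1. **Tiling.** Each 20× acquisition (nominally 1653 × 1239 px) is cut into
   non-overlapping 110 × 110 px tiles on a top-left-anchored grid
   (15 × 11 = 165 tiles per full image); margins are discarded.
2. **Features (134 per tile).**
   - *Color (39):* the tile is mapped to HSV and each channel is summarised
     by 13 first-order statistics (mean, median, min, max, range, variance,
     mean absolute deviation, RMS, skewness, kurtosis, energy, entropy,
     uniformity).
   - *Texture (43):* the luminance image (0.299 R + 0.587 G + 0.114 B) is
     quantized to Ng = 32 gray levels and summarised by 21 gray-level
     co-occurrence (GLCM, P(i,j|δ,θ), δ = 1, averaged over
     θ ∈ {0°, 45°, 90°, 135°}), 11 run-length (GLRLM, P(i,j|θ), angle-
     averaged) and 11 size-zone (GLSZM, 8-connected zones, single
     rotation-independent matrix) features.
   - *Wavelet (52):* a one-level 2D DWT with the 8-tap least-asymmetric
     Daubechies filter splits the image into LL/LH/HL/HH quarter-size
     subbands; each gets the 13-statistic panel.
3. **Cascade classification.** Stage 1 separates analyzable *tissue* from
   *waste* tiles (artifacts, bubbles, folds, connective tissue); stage 2
   separates *ragged* from *not-ragged* among tissue tiles. For each stage,
   random forest, gradient boosting, and RBF-SVM are tuned by random search
   under stratified 10-fold cross-validation on an 80 % training split
   (selection by mean F1), retrained, and compared by test-set AUC; the
   winner becomes the stage model. Features are z-scored inside every fold's
   training portion only. At prediction time a tile is *waste* if
   p(tissue) < 0.5, otherwise *ragged* iff p(ragged) ≥ 0.5.

Because no public RRF image set exists, the package ships a synthetic tile
generator producing the three classes (green fiber mosaic; mosaic with red
granular rim; pale background with artifacts) with a single separation dial
`s ∈ [0, 1]`, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from rrfdetect import (SyntheticConfig, generate_dataset, train_cascade,
                       predict_cascade, default_learners)
from rrfdetect.pipeline import extract_feature_table

tiles, manifest = generate_dataset(
    {"waste": 40, "ragged": 30, "not_ragged": 30},
    SyntheticConfig(separation=1.0), seed=3)
table = extract_feature_table(tiles)          # 100 x 134 features + label
model = train_cascade(table, learners=default_learners(n_iter=3), seed=1)
for name, stage in [("waste/tissue", model.stage1),
                    ("ragged/not-ragged", model.stage2)]:
    print(name, stage.selected,
          {k: round(v.test_auc, 3) for k, v in stage.candidates.items()})
print(predict_cascade(model, table)["label"].value_counts().to_dict())
```

prints

```
waste/tissue random_forest {'random_forest': 1.0, 'gradient_boosting': 1.0, 'svm_rbf': 1.0}
ragged/not-ragged random_forest {'random_forest': 1.0, 'gradient_boosting': 1.0, 'svm_rbf': 1.0}
{'waste': 40, 'ragged': 30, 'not_ragged': 30}
```

i.e. on well-separated synthetic tiles every candidate reaches test AUC 1.0
(ties are broken in favour of the first learner) and the cascade labels all
100 tiles correctly.

A CLI mirrors the library: `rrfdetect simulate|tile|extract|train|predict|evaluate --help`.

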
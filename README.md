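# codalign

Semi-supervised segmentation of class-imbalanced biomedical images by
**co-distribution alignment**: two differently initialised networks
co-train on a small labeled set plus unlabeled images, each supervising
the other with pseudo-labels. Each network maintains class-wise labeled
and unlabeled marginal prediction distributions (K×K matrices `Ml`, `Mu`,
updated by exponential moving average), rescales its unlabeled
predictions by `Ml_i^τi ⊘ Mu_i` (with adaptive temperature
`τi = 1 − Ml[i,i]`) before pseudo-labeling, and keeps only pseudo-labels
whose confidence strictly exceeds the dynamic per-class threshold
`t(i) = Mu[i,i]` (the over-expectation filter). This counteracts the
majority-class bias that plain pseudo-labeling develops when labels are
scarce and classes are unevenly distributed.

The package is aimed at method researchers who want a compact, fully
deterministic, CPU-only reference implementation: a numpy backbone with
manual gradients, a synthetic imbalanced-task generator, standard
segmentation metrics (mIoU, Dice, Jaccard, ASD, HD, 95HD), a sklearn-style
estimator, and a CLI.

## Worked example

```python
import numpy as np
from codalign import CoDASegmenter, SyntheticDatasetSpec, generate

bundle = generate(SyntheticDatasetSpec(seed=1))     # K=4, 64 images, 12% labeled
Xl, yl = bundle.labeled_arrays()
Xu = bundle.unlabeled_images()
X = np.concatenate([Xl, Xu])
y = np.concatenate([yl.astype(np.int64), np.full(Xu.shape, -1, dtype=np.int64)])

xt, yt = bundle.test_arrays()
coda = CoDASegmenter(seed1=11, seed2=12, data_seed=1).fit(X, y)
sup = CoDASegmenter(seed1=11, seed2=12, data_seed=1, supervised_only=True).fit(X, y)
print("co-da mIoU      ", round(coda.score(xt, yt.astype(np.int64)), 3))
print("supervised mIoU ", round(sup.score(xt, yt.astype(np.int64)), 3))
print("co-da per-class IoU", np.round(coda.per_class_iou(xt, yt.astype(np.int64)), 3))
```

Output:

```
co-da mIoU       0.749
supervised mIoU  0.729
co-da per-class IoU [0.906 0.609 0.696 0.787]
```

Masks with every pixel set to −1 mark unlabeled images. The test mIoU of
the full method exceeds the supervised-only baseline trained on the same
8 labeled images, and the gain concentrates on the rarer foreground
classes (classes 2 and 3 cover only a few percent of pixels each).

The same experiment from the shell:

```
codalign simulate --out data --num-classes 4 --num-images 64 --labeled-frac 0.12 --seed 1
codalign train --data data --out run --iterations 1000
codalign eval --pred preds/ --gt gts/ --num-classes 4 --metrics miou,dice,asd
```

Ablation flags: `--no-align` (skip the distribution transformation),
`--no-oe` (accept all pseudo-labels), `--supervised-only`,
`--static-threshold T` (replace the dynamic thresholds with a constant).

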
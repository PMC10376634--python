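# Methods

## Problem setting

Semi-supervised semantic segmentation of biomedical images: a small set of
images carries pixel-wise class masks, a larger set is unlabeled, and the
class distribution is strongly imbalanced (background dominates; clinically
relevant structures are rare). Naive pseudo-labeling in this regime is
biased toward majority classes — a network trained on few labels
pseudo-labels almost everything background, and self-training then
reinforces the bias. The package implements a co-training method that
counteracts this by aligning the *class-wise* statistics of predictions on
unlabeled data to the statistics observed on labeled data, and by filtering
pseudo-labels with a dynamic, per-class confidence threshold.

## Model

Two networks `F1`, `F2` with identical architecture and different random
initialisations are trained jointly. On labeled pixels both minimise the
standard cross-entropy

    Ls = mean_x [ -log F1(x)_y - log F2(x)_y ].

On unlabeled pixels each network is supervised by the *other* network's
hard pseudo-labels (cross-pseudo supervision). Before pseudo-labels are
taken, each network's unlabeled predictions are transformed by
class-wise distribution alignment:

- Each network maintains two K×K matrices by exponential moving average
  (EMA, momentum α): row i of `Ml` is the running conditional mean of its
  probability vectors over labeled pixels with ground-truth class i; row i
  of `Mu` is the same over unlabeled pixels whose argmax class is i.
- A class absent from an unlabeled batch (typically a minority class) is
  refreshed through the average labeled→unlabeled transformation: its
  labeled row is multiplied entrywise by the mean over all K classes of
  `Mu_j / Ml_j` and renormalised.
- For a pixel with argmax class i, the prediction `p` is replaced by
  `Normalize(p ⊗ Ml_i^τi ⊘ Mu_i)` with the adaptive temperature
  `τi = 1 − Ml[i,i]` (clamped to `[tau_min, 1]`). Confidently learned
  classes get a small τ, flattening their labeled row so the alignment is
  dominated by the inverse unlabeled marginal and minority classes are not
  suppressed.

Pseudo-labels are the argmax of the aligned map; a pixel participates in
the unsupervised loss only if its aligned confidence *strictly* exceeds the
dynamic per-class threshold `t(i) = Mu[i,i]` — the network's own expected
confidence for that class ("over-expectation" filtering). The unsupervised
loss for one direction is the mean over **all** unlabeled pixels of
`accept · (−log p_self[pseudo-label])`; rejected pixels contribute zero but
stay in the denominator, so raising thresholds can only shrink the loss.
Both directions are summed and the total `Ls + λu·Lu` is applied to both
networks each iteration (λu = 1 by default).

One deliberate design choice: the alignment transformation steers
*pseudo-label generation only*; the cross-entropy itself (and its gradient)
is applied to the network's own **raw** prediction. This keeps the
alignment switch isolated to pseudo-labels/confidences — an invariant the
ablation tests rely on — and avoids an instability we observed with the
alternative (putting the aligned map inside the logarithm): alignment
inflates minority probabilities at majority-pseudo-labeled pixels, so the
cross-entropy toward the majority label then actively suppresses minority
logits, and training collapses to the background class.

Because pseudo-labels, masks and alignment weights are detached statistics,
every gradient is a (masked) softmax cross-entropy gradient on a network's
own logits; the backward pass needs no general autodiff.

## Iteration order

Per iteration, in this fixed order: sample a labeled and an unlabeled
batch; for each network update `Ml` from the labeled batch, then `Mu` from
the raw unlabeled predictions; align the unlabeled predictions; build
pseudo-labels and acceptance masks; compute `Ls` and `Lu`; one SGD-momentum
step per network on `Ls + λu·Lu`. Matrices are initialised uniform (1/K),
which makes alignment an exact no-op at step 0.

## Backbone

The bundled reference backbone is a tiny U-Net written directly in numpy
(im2col convolutions, manual backward passes): conv3×3 → ReLU → 2×2
max-pool → conv3×3 → ReLU → nearest upsample → skip concatenation →
conv3×3 → ReLU → 1×1 K-way softmax head, width 8 by default, He
initialisation from a seeded generator. At the raster sizes the package
targets (tens of pixels per side) this trains in milliseconds per
iteration on one CPU and is fully deterministic. Larger backbones are
pluggable via the same forward/backward interface.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| α (TrainConfig) | 0.999 | EMA momentum of `Ml`/`Mu`. The statistics must evolve slowly relative to the network. The tiny backbone adapts in ~50 iterations; a time constant of ~1000 iterations restores the slow-statistics/fast-network separation that large backbones get for free. The standalone `EMAConfig` default is 0.99 (~100 batches), appropriate when the network itself is slow. |
| tau_min | 0.05 | Lower clamp of τ; τ→0 with a zero labeled entry is ill-conditioned. |
| ε | 1e-8 | Guard added to every divisor; 0^τ is evaluated as ε^τ. |
| λu | 1.0 | Unsupervised loss weight; no warm-up ramp is applied. |
| learning rate | 0.02 | SGD with momentum 0.9, constant by default (optional polynomial decay). 0.02 is the fastest rate at which the alignment feedback loop stayed stable on the reference task; 0.05 and above produced runaway pseudo-label feedback. |
| iterations | 1000 | Reference run length; training loss and validation mIoU plateau well before this on the reference task. |
| batch sizes | 4 + 4 | Labeled and unlabeled sub-batches, drawn independently with wraparound shuffling. |
| static_threshold | None | Replaces `t(i)=Mu[i,i]` with one scalar, for threshold ablations. |

Alignment weight rows are rescaled by their maximum before use. The final
per-pixel normalisation is invariant to row scale, so this changes nothing
mathematically, but it improves conditioning and makes the
uniform-matrices case an exact (bit-level) identity.

## Synthetic reference task

The generator emulates the two properties that make this regime hard —
strong class imbalance and a tiny labeled subset — not the appearance of
any real modality. Defaults: K=4 classes, 64 images of 32×32, 12% labeled
(8 images), 20% test. Foreground classes are random ellipses whose
expected total area decays geometrically with class index (ratio 0.4);
shape counts are Poisson, so minority classes are genuinely absent from
some images, exercising the absent-class update branch. Pixel intensity is
the class mean (evenly spread over [0.15, 0.9]) plus Gaussian noise of
σ = 0.30, quantised to 8 bits. The noise level was chosen so that the
supervised-only baseline visibly under-fits (~0.66 mean mIoU) — a regime
where unlabeled data can plausibly help — while local context still makes
the task learnable; it was selected by inspecting supervised baselines
only. The labeled subset size is `max(1, round(fraction · num_images))`.

What the generator does **not** emulate: anatomical shape priors, texture,
inter-image intensity shifts, annotation noise, 3D volumes (3D is covered
on the metric side only). Passing tests therefore demonstrate the
machinery and its direction of effect at desk scale, not clinical-level
performance.

## Evaluation metrics

Overlap: per-class confusion counts give IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN), Jaccard = IoU; mIoU averages IoU over classes with
nonzero union (classes absent from both rasters are excluded). Surface
distances: a foreground element is a surface element iff it has a
face-adjacent background neighbour or lies on the raster border; distances
are Euclidean with optional anisotropic spacing, nearest neighbours via a
k-d tree. ASD is the symmetric mean of directed nearest-surface distances;
HD the max of the two directed maxima; 95HD replaces each directed max
with the 95th percentile (linear interpolation) and takes the larger — a
pooled-percentile variant is available via `method="pooled"`. Empty
surfaces raise an error naming the empty side.

## Numerical and degenerate-input choices

- Probabilities are floored at 1e-12 inside logarithms; losses are finite
  for any simplex input.
- A labeled class absent from a batch keeps its row unchanged (the
  inverse-transform refresh applies only to the unlabeled matrix).
- `t(i)` comparison is strictly greater-than, so a threshold of 1
  rejects everything and a threshold of 0 accepts everything (confidence
  ≥ 1/K > 0), reducing the O-E loss to plain cross-pseudo supervision.
- Thresholds come from the pseudo-label-generating network's own `Mu`.
- `supervised_only` forces the alignment and O-E switches off.
- Determinism: all randomness flows from explicit seeds (two model seeds,
  one data seed); identical configs give bit-identical training logs, and
  checkpoint resume reproduces an uninterrupted run exactly.

## Reference experiment

`scripts/acceptance.py` trains the full method and the supervised-only
baseline for 1000 iterations on three generated instances of the reference
task and reports mean test mIoU, mean foreground IoU, their difference,
and the final pseudo-label acceptance fraction. Problem sizes (64 images,
32×32, 1000 iterations, three seed triplets) are the package's reference
desk-scale configuration; the direction of the comparison, not its
magnitude, is the claim being checked.

## Known limitations

- The backbone is intentionally tiny; absolute scores on the synthetic
  task say nothing about real datasets or large backbones.
- The reference comparison is noisy at this problem size (three seed
  triplets, 13 test images each): the sign of the mIoU difference between
  the full method and the supervised baseline can vary across seed
  triplets, so single runs should be read as direction-of-effect evidence
  under the reference conditions, not as a stable effect size.
- The EMA momentum appropriate for a backbone depends on how fast that
  backbone moves; the 0.999 default is calibrated to the bundled one.
- The absent-class refresh averages the ratio over all K rows, including
  the stale row being refreshed (deterministic and simple; a
  present-rows-only variant would be a one-line change).
- 2D training only; surface metrics support 3D rasters.
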
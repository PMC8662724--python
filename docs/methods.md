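# Methods

This note documents the modeling and numerical choices behind
`maffresunet`, the assumptions they rest on, and what the bundled phantom
experiments do and do not demonstrate.

## Data model and preprocessing

A case is four co-registered, skull-stripped scalar volumes (T1, T1ce, T2,
Flair) plus an integer label volume over {0, 1, 2, 4}. Label 3 does not
exist in this convention and is rejected at read time. The evaluation
subregions are nested unions of labels: WT = {1,2,4}, TC = {1,4},
ET = {4}; targets are therefore encoded as three *overlapping* binary
channels with independent sigmoid outputs, not as a 4-class softmax — the
head and the BCE term require it, and it makes the nesting a property of
the label mapping rather than of the network.

Per modality volume, in order:

1. **Winsorization** to the 1st/99th percentile. Percentiles are computed
   over nonzero (brain) voxels, and the clamp is applied to those voxels
   only. Clamping background zeros up to the 1st percentile would make the
   skull-stripped exterior nonzero and destroy the brain mask that the
   next step depends on, so the background is left at exactly 0.
2. **Z-score normalization** z = (x − μ)/σ with μ, σ over the brain
   voxels; background stays 0. The invariant (brain mean 0, SD 1 within
   1e-4) is tested against a two-pass oracle. σ = 0 is a hard error.
   Statistics are per-volume, not per-dataset.
3. **Axial slicing** along the first axis; slices whose label plane is all
   background are dropped (the same filter for train/val/test).
4. **Center crop** to crop_size² (default 160, so rows/cols 40..199 of a
   240² plane). Cropping happens after normalization, so the statistics
   are those of the full brain.
5. **Channel stacking** in fixed order T1, T1ce, T2, Flair.

The train/val/test split is at slice level (fractions 0.8/0.1/0.1, seeded
shuffle, train takes rounding remainders). Slice-level splitting means
slices of one subject can appear in different partitions; that matches the
slice-based design of the pipeline but inflates val/test scores relative
to subject-level splits — one reason the phantom numbers say nothing about
clinical performance.

## Architecture

Defaults: base_filters b = 32 with per-level doubling (32/64/128/256,
intermediate 512) and fusion_channels C = 32. Channel widths are the
canonical U-Net doubling scheme; nothing in the architecture fixes them,
and tests run at b ∈ {2, 4, 8} — the network is fully convolutional, so
any input size divisible by 16 works.

Choices worth flagging because the architecture description admits more
than one reading:

* **Softmax axis.** The attention map A_i is normalized across its C
  channels at each spatial location. The AFB ends in a 1×1 convolution,
  so a per-location channel softmax is the natural normalization that
  also makes A_i broadcastable against F_m: each of A_i's C channels
  weights the four corresponding level-channels of the 4C-channel hybrid
  map (A_i is tiled 4× along channels). This is the package's main
  interpretive decision and is isolated in
  `AttentionFeatureBlock.forward` / `MAFFResUNet.apply_attention`.
* **"Multiplication" of A_i with F_m** is broadcast elementwise
  weighting. The shapes involved (a spatial attention map, a 4C×H×W
  hybrid, a C×H×W refined result) admit no literal matrix product.
* **f_up** is 4× bilinear up-sampling — exactly undoing the two 2×
  average poolings inside g, forced by the requirement that A_i align
  with F_m.
* **Residual shortcut** is a 1×1 projection convolution when channel
  counts differ, identity otherwise (ResNet option B). With all residual-
  branch weights zeroed, an encoder block reduces to
  ReLU(shortcut(x)) — tested as a wiring check.
* **Fusion head**: each refined map gets its own 1×1 class-logit
  convolution; the four *logit* maps are averaged before the sigmoid,
  keeping the head linear up to the output nonlinearity.
* Each of the four AFBs has independent parameters; PReLU uses one
  learnable slope per layer, initialized at 0.25. Convolutions are
  He-normal initialized; BN uses batch statistics in training and running
  statistics (momentum 0.1) in eval.

## Loss

Loss = α·BCE + β·soft-Dice with α = 0.5, β = 1, ε = 1e-5, computed per
subregion channel and averaged, weighting WT/TC/ET equally. Predictions
enter the Dice term as probabilities (soft Dice) — thresholding would kill
the gradient. Probabilities are clamped to [1e-7, 1−1e-7] before the BCE
logs; the clamp gradient is zero outside the interval, which keeps the
total gradient finite on [0, 1]. The ε in the Dice term makes the
empty-prediction/empty-target case a loss of 0 rather than 0/0.

## Optimization

Adam with β₁ = 0.90 (the configuration's "momentum" maps onto Adam's
first-moment coefficient; Adam has no classical momentum), β₂ = 0.999,
coupled weight decay 1e-4 added to the gradient. Learning rate follows the
poly policy lr = lr_init·(1 − iter/max_iter)^0.9 evaluated every step.
Defaults lr_init = 3e-4, batch 16 describe the full-data regime;
`max_iter` must be set by the user since no canonical epoch count exists.
Model selection is by best mean validation DSC over the three subregions,
evaluated every `checkpoint_every` steps. All randomness (init, shuffling)
derives from config seeds; everything is float64 single-threaded numpy, so
two runs with the same seeds are bit-identical.

## Metrics

IoU, SEN, PPV, DSC from pixel counts; HD is the exact symmetric maximum
Hausdorff distance (not HD95) between boundary pixel sets (mask minus its
4-connectivity erosion), Euclidean, scaled by pixel spacing (default 1 mm
isotropic). Conventions where the definitions are silent: both-empty masks
score IoU = DSC = 1 (agreement on absence); empty-G slices are skipped for
SEN, empty-P for PPV, either-empty for HD, with skip counts surfaced in
the report. Hard masks use threshold 0.5 with ≥ at the boundary, each
channel thresholded independently (nesting is not enforced post hoc).
Aggregation is slice-level mean ± SD; all five metrics are tested exactly
against brute-force set-arithmetic / double-loop oracles.

## Phantom generator

Phantoms are ellipsoidal: a brain ellipsoid of nonzero tissue containing
three concentric tumor ellipsoids (ET inside TC inside WT, semi-axis
ratios 0.35/0.65/1.0, outer in-plane radius drawn uniformly from
`tumor_radius_range`). Modalities differ by per-tissue mean intensity
(Flair-bright edema, T1ce-bright enhancing rim, T2-bright fluid) with
Gaussian noise of SD 0.05 against tissue contrasts of order 0.3–0.9 —
clearly separable classes. Default volume 32×96×96 so CPU pipelines run in
seconds; full 155×240×240 generation only needs a different `shape`.

What phantoms do *not* emulate: MRI physics (bias fields, partial volume,
acquisition noise structure), irregular tumor shapes and infiltrative
boundaries, inter-subject anatomy, class-imbalance statistics of real
gliomas. Passing phantom tests therefore demonstrates that the pipeline is
*correct* (shapes, gradients, losses, metrics, determinism) and *able to
learn* a separable segmentation — not that the model reaches any
particular accuracy on clinical data.

## Desk-scale experiment

The reproducible experiment in `maffresunet.experiments` trains the
reduced-width network (b = C = 8) on 8 phantom slices (64×64 crops from
two phantoms, slices spread evenly over the tumor extent) for 200 Adam
steps at batch 4 with lr_init = 5e-3 under the poly schedule, then
evaluates on those same slices. This is deliberately an *overfitting*
experiment: its success criteria are a large training-loss reduction and
near-perfect training-set Dice, which exercise every stage end to end.
lr_init = 5e-3 rather than the full-data 3e-4 reflects the regime: 200
small-batch steps on 8 easy samples reward a much more aggressive step
size, and 3e-4 does not converge meaningfully within the step budget. The
batch size of 4 matches the 8-slice sample (two mini-batches per epoch).
Problem sizes (8 slices, 64² crops, width 8, 200 steps) were chosen so the
experiment completes in a few minutes on one CPU core.

## Known limitations

* The autodiff engine is stride-1/2D only and float64 single-threaded —
  intentionally small and verifiable, not fast; GPU-scale training of the
  full-width model is out of scope.
* No data augmentation, no 3D context, no HD95 or surface-distance
  variants, no baseline architectures (FCN, plain U-Net).
* Slice-level splitting (see above) is the documented default; subject
  level splitting can be built from the per-case slice lists if needed.
* Max-pool gradient routing breaks ties by first occurrence; with
  continuous inputs ties have measure zero.
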
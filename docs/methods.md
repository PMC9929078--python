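# Methods

## Problem and model

`cellcount` studies segmentation-free cell counting: a convolutional network
regresses the number of cells in a grayscale brightfield-like field directly
from pixels. The reference architecture is

    [Conv2D(kernel 3, valid padding, ReLU) -> MaxPool(2x2, stride 2)] x 4
    with filter counts 32 / 64 / 128 / 256,
    Flatten -> Dropout(rate 0.90) -> Dense(1, ReLU)

trained with MSE loss. Valid padding and pooling shrink the spatial side as
`s -> floor((s - 2) / 2)` per block, so a 200x200 input passes through
99 -> 48 -> 23 -> 10 before flattening. The single ReLU output neuron keeps
predictions non-negative, as counts are. A dropout rate of 0.90 directly
after Flatten is unusually aggressive; it is the reference setting and is
configurable in `ModelSpec`.

The network is built on the package's own numpy CNN engine (`cellcount.nn`):
im2col convolutions evaluated as single BLAS matmuls, 2x2 argmax pooling,
inverted dropout, Adam, and early stopping. A finite-difference gradient
check of the full stack is part of the test suite.

## Training procedure

- Optimizer Adam; batch size 32. Learning rate defaults to 1e-3 in
  `TrainConfig`; the packaged experiments use 3e-3, which converges in tens
  of epochs at their problem size. Gradients are clipped to a global norm of
  5.0: without clipping, the large first Adam steps occasionally drive the
  output unit's pre-activation permanently below zero (a dead output ReLU,
  i.e. constant zero predictions). If a model nevertheless collapses to a
  constant, `run_experiment` records it as Pearson r = 0, p = 1 (no
  measurable linear association) rather than aborting the study; the metric
  functions themselves still treat zero variance as undefined.
- **Label scaling.** Count labels span roughly 3-600 while the optimiser's
  step size is tuned for order-one targets, so `train()` divides labels by a
  scale (default `"auto"` = mean training label) during optimisation and
  multiplies predictions back. All reported errors are in raw count units.
  The output bias is initialised to 1.0 so the ReLU output unit starts alive
  at the scaled-label mean. Set `label_scale=None` to regress raw counts.
- **Early stopping** monitors the test-bank MSE each epoch, stops after
  `patience` (default 20; experiments use 10) epochs without improvement, and
  restores the best weights. Monitoring the *test* bank conflates validation
  and test — it reproduces the evaluation protocol this package studies and
  is kept deliberately; pass a separate validation bank to `train()` for a
  clean protocol.
- Training is deterministic given the config seeds (single-threaded BLAS).

## Synthetic data: what it emulates and what it does not

Each field is background + a linear illumination ramp (random direction,
amplitude in grayscale units) + one radially symmetric Gaussian blob per
cell (sigma = radius/2, truncated at 3 sigma) + i.i.d. Gaussian pixel noise,
clipped to [0,1]. Cell radii are drawn around 1.4% of the field side, so
cells keep a realistic size relative to the field of view. Counts are drawn
uniformly over a configurable range, default 50-600 per full field — the
count scale is an assumption recorded in config, chosen so per-image errors
in the hundreds are possible, not a measured property of any real dataset.

Two regimes:

- `high_contrast` (A549/Huh7-like): cells ~0.40 darker than the 0.65
  background with +-0.10 per-cell jitter, no appreciable overlap, gradient
  amplitude 0.05, noise sigma 0.02.
- `low_contrast_confluent` (3T3-like): per-cell offsets of magnitude ~0.03
  with *random sign*, so the mean cell intensity equals the background and
  integrated intensity carries almost no count information; overlap allowed;
  gradient amplitude 0.12 (larger than the cell signal); noise sigma 0.02.

Not emulated: phase-contrast optics (halos, shade-off), cell morphology and
texture, debris, focus drift, vignetting beyond a linear ramp. Passing tests
therefore show that the pipeline recovers counts when blob-like signal is
present and degrades when contrast vanishes; they do not certify performance
on real instrument images.

## Augmentation and label rescaling

Crops come first (the 4x intermediate bank), then orientations, then the
resize — so the scale-only banks (284/208/176 from 71/44/52) exist as real
objects for ablations. Crops are deterministic centre crops; an `origin`
argument supports randomised-position studies. The label of a crop is
rescaled by the **retained area** (count x fraction^2) by default: for a
spatially uniform field the expected retained count is proportional to area.
A `linear` mode (count x fraction) and an `exact_recount` mode (synthetic
scenes only; counts centres inside the window) exist for fidelity checks,
and a Monte-Carlo test confirms area-mode labels match the recount
expectation. Labels are real-valued after rescaling. Resizing changes
resolution, not field of view, so it never changes the label.

The random split acts on the augmented bank, so near-duplicate variants of
one source image can land on both sides of the split — again the studied
protocol, reproduced as published; `split(..., group_by_source=True)` keeps
all variants of a source together as a documented deviation.

Split sizes use `n_train = floor(train_fraction * N)`: it is the unique
rounding rule consistent with all three reference splits (floor(0.7 x 1136)
= 795, floor(0.7 x 704) = 492, floor(0.7 x 832) = 582).

## Packaged experiment sizes

The packaged studies (`cellcount.pipeline`, `scripts/acceptance.py`, the
acceptance tests) run the identical pipeline at a scaled-down geometry chosen
so a full run takes about a minute on one CPU core: 256-pixel fields,
64-pixel network inputs, filter widths 8/16/32/64, learning rate 3e-3, at
most 70 epochs with patience 10. Dropout (0.90), kernel, pooling, padding,
the 16x augmentation, area labels and the floor-0.7 split are unchanged.
`ModelSpec()` defaults remain the full-size reference configuration
(200x200, 32/64/128/256) for users who want to train it.

## Numerical choices and degenerate inputs

- Pixels are float32 in [0,1] in memory; 16-bit PNG on disk (one 65535th
  quantisation on the first save; round-trips thereafter are bit-exact).
- Pooling ties share the gradient equally; trailing odd rows/columns are
  dropped (valid pooling).
- R² and Pearson r raise `UndefinedMetricError` when the observed (or
  either) series has zero variance; the Pearson p-value is the exact
  two-sided t transform with n-2 degrees of freedom, rejected at p < 0.01.
- A scene with zero cells renders to background + ramp (+ noise); a contrast
  of exactly 0 requires the mean cell intensity to equal the background.
- Non-overlapping placement uses dart throwing with 40 retries per cell and
  then places the cell regardless, so the requested count is always honoured.

## Known limitations

- The numpy engine is CPU-only and single-threaded; the full-size reference
  network is impractical to train with it (hours, not minutes).
- Blob renderings cannot probe texture-based counting cues.
- The low-contrast regime's count recovery (R ~ 0.3-0.45 here) sits above
  the near-zero correlation seen on real confluent cultures, because even
  sign-symmetric blobs leave a variance cue; the qualitative collapse
  relative to the high-contrast regime is the studied effect.
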
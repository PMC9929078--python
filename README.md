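# cellcount

Segmentation-free cell counting in brightfield (digital contrast) microscopy
images with a small convolutional neural network.

High-content screening instruments acquire label-free transmitted-light
images in which cells show weak, heterogeneous contrast; counting them
without fluorescent nuclear markers avoids phototoxicity but defeats
intensity-threshold segmentation. `cellcount` treats the problem as *count
regression*: a CNN maps a whole grayscale field directly to the number of
cells in it, trained on images whose counts are known.

The package is a complete, reproducible pipeline for studying when that
works:

- **`cellcount.synthgen`** — synthetic brightfield-like fields with exactly
  known counts, in two regimes: well-contrasted blob-like cells
  (`high_contrast`) and a confluent regime where cell intensity matches the
  background (`low_contrast_confluent`).
- **`cellcount.augment`** — two-stage augmentation: centre crops at
  100/75/50/25% of linear size with the count label rescaled in proportion to
  the retained area, then horizontal/vertical/both flips, then resize to the
  network input. A bank grows 16× (71 → 1,136 images; the scale-only stage
  gives the intermediate 4× banks, e.g. 284).
- **`cellcount.datasets`** — bank manifests (CSV + 16-bit PNG), the
  floor-rule 70/30 random split (1,136 → 795/341), and bank subsampling for
  size ablations.
- **`cellcount.model`** — the regressor: four `Conv(3×3, valid, ReLU) →
  MaxPool(2×2, stride 2)` blocks with filters 32/64/128/256, `Flatten →
  Dropout(0.90) → Dense(1, ReLU)`, MSE loss, Adam, early stopping on
  validation MSE with best-weight restore. Built on the package's own
  numpy CNN engine (`cellcount.nn`).
- **`cellcount.evaluate`** — MSE, MAE, R² score, and the Pearson correlation
  test between observed counts Y_i and predictions Ŷ_i
  (MSE = n⁻¹ Σ (Y_i − Ŷ_i)², R² = 1 − SS_res/SS_tot,
  t = r√((n−2)/(1−r²)) against H₀: no correlation), plus ablation tables and
  correlation plots.
- **`cellcount.pipeline`** — one-call end-to-end experiments and the
  bank-size × split-fraction ablation grid.

## Worked example

```python
from cellcount.pipeline import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(regime="high_contrast", seed=0))
r = result.report
print(f"test MSE {r.mse:.0f}  MAE {r.mae:.1f}  R2 {100*r.r2_score:.1f}%  "
      f"R {r.pearson_r:.3f}  stopped at epoch {result.history.stopped_epoch}")
```

prints (71 synthetic originals → 1,136 augmented images → 795 train / 341
test, ~70 s on one CPU core):

```
test MSE 1560  MAE 31.1  R2 91.9%  R 0.967  stopped at epoch 47
```

MSE/MAE are in squared-count and count units on the held-out bank; R is the
Pearson correlation between true and predicted counts (here strongly
positive, p < 0.01). Rerunning with
`regime="low_contrast_confluent"` gives R ≈ 0.41 — count recovery collapses
when cells match the background intensity — and subsampling the augmented
bank to 176 images (`subsample_n=176`) raises the held-out MSE more than
fourfold, reproducing the bank-size effect.

The same stages are available from the shell:

```sh
cellcount generate --regime high_contrast --n-images 71 --field 1080 --seed 11 --out bank/
cellcount augment --in bank/ --out bank16x/ --target 200
cellcount run --regime high_contrast --seed 0 --out run0/
cellcount ablate --grid none:0.7,176:0.7,176:0.6 --out ablation/
```

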
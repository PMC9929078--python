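"""End-to-end count-recovery experiments: generate -> augment -> split ->
train -> evaluate, plus the bank-size/split-fraction ablation grid.

An experiment draws a bank of synthetic fields with known counts, expands it
16x with the crop/flip augmentation (area-rescaled labels), splits the
augmented bank 70/30 (optionally subsampling it first, the bank-size
ablation), trains the CNN regressor with early stopping against the test
bank, and evaluates held-out count recovery.

The default experiment geometry is a scaled-down instance of the same
pipeline: 256-pixel fields, 64-pixel network inputs and filter widths
8/16/32/64, sized so that a full run takes tens of seconds on one CPU core
(see docs/methods.md).  Every knob is exposed for larger runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .augment import AugmentConfig, expand_bank
from .datasets import SplitSpec, split, subsample
from .errors import UndefinedMetricError
from .evaluate import (EvalReport, PredictionSet, evaluate_predictions, mae,
                       mse, r2_score)
from .model import (CountRegressor, ModelSpec, TrainConfig, TrainHistory,
                    build_model, predict, train)
from .synthgen import generate_bank

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "small_model_spec",
    "small_train_config",
    "run_experiment",
    "run_ablation",
]


def small_model_spec(input_size: int = 64) -> ModelSpec:
    """The default scaled-down regressor: same architecture family, thinner."""
    return ModelSpec(conv_blocks=(8, 16, 32, 64),
                     input_size=(input_size, input_size, 1))


def small_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(max_epochs=70, patience=10, learning_rate=3e-3, seed=seed)


@dataclass(frozen=True)
class ExperimentConfig:
    regime: str = "high_contrast"
    n_originals: int = 71
    field_size: int = 256
    count_range: tuple = (50, 600)
    target_size: int = 64
    label_scaling_mode: str = "area"
    subsample_n: Optional[int] = None     # bank-size ablation: shrink after augmenting
    train_fraction: float = 0.70
    conv_blocks: tuple = (8, 16, 32, 64)
    dropout_rate: float = 0.90
    max_epochs: int = 70
    patience: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 32
    seed: int = 0


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    report: EvalReport
    history: TrainHistory
    train_size: int
    test_size: int
    predictions: PredictionSet
    model: CountRegressor = None


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def run_experiment(config: ExperimentConfig = ExperimentConfig(),
                   keep_model: bool = False) -> ExperimentResult:
    """Run one full pipeline pass and evaluate held-out count recovery."""
    gen_seed, split_seed, sub_seed, train_seed, init_seed = _derive_seeds(config.seed, 5)

    bank, scenes = generate_bank(config.regime, config.n_originals,
                                 config.count_range, config.field_size,
                                 gen_seed, return_scenes=True)
    aug = AugmentConfig(target_size=config.target_size,
                        label_scaling_mode=config.label_scaling_mode)
    expanded = expand_bank(bank, aug, scenes=scenes)
    if config.subsample_n is not None:
        expanded = subsample(expanded, config.subsample_n, sub_seed)
    train_bank, test_bank = split(expanded,
                                  SplitSpec(config.train_fraction, split_seed))

    spec = ModelSpec(conv_blocks=config.conv_blocks,
                     dropout_rate=config.dropout_rate,
                     input_size=(config.target_size, config.target_size, 1))
    model = build_model(spec, seed=init_seed)
    tcfg = TrainConfig(learning_rate=config.learning_rate,
                       batch_size=config.batch_size,
                       max_epochs=config.max_epochs,
                       patience=config.patience,
                       seed=train_seed)
    history = train(model, train_bank, test_bank, tcfg)
    preds = predict(model, test_bank)
    pred_set = PredictionSet(observed=test_bank.counts(), predicted=preds,
                             bank_tag=f"{config.regime}/test")
    try:
        report = evaluate_predictions(pred_set)
    except UndefinedMetricError:
        # a collapsed model predicting a constant has no measurable linear
        # association; score it as zero correlation rather than aborting a study
        report = EvalReport(mse=mse(pred_set), mae=mae(pred_set),
                            r2_score=r2_score(pred_set), pearson_r=0.0,
                            p_value=1.0, h0_rejected_at_0p01=False,
                            n=pred_set.n, bank_tag=pred_set.bank_tag)
    return ExperimentResult(config=config, report=report, history=history,
                            train_size=len(train_bank), test_size=len(test_bank),
                            predictions=pred_set,
                            model=model if keep_model else None)


def run_ablation(base: ExperimentConfig,
                 grid: list[tuple[Optional[int], float]]) -> list[ExperimentResult]:
    """Run the bank-size x split-fraction grid; each entry is (subsample_n, train_fraction)."""
    results = []
    for subsample_n, train_fraction in grid:
        cfg = ExperimentConfig(**{**base.__dict__,
                                  "subsample_n": subsample_n,
                                  "train_fraction": train_fraction})
        results.append(run_experiment(cfg))
    return results
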
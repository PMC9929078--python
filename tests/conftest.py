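"""Shared fixtures.

The expensive end-to-end training runs (three seeds x three study conditions)
are computed once per session and shared by every test that needs them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellcount.datasets import Bank, LabeledImage
from cellcount.pipeline import ExperimentConfig, run_experiment

STUDY_SEEDS = (0, 1, 2)


def tiny_bank(n: int, side: int = 8, counts=None, seed: int = 0) -> Bank:
    """A bank of n flat little images, for size/bookkeeping tests."""
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = rng.integers(0, 100, size=n)
    items = [
        LabeledImage(pixels=rng.random((side, side)).astype(np.float32),
                     count=float(c), line_tag="tiny", meta={"source_index": i})
        for i, c in enumerate(counts)
    ]
    return Bank(items=items)


@pytest.fixture(scope="session")
def study_runs():
    """Full-pipeline results for the three study conditions at three seeds.

    Conditions: high-contrast full bank, low-contrast-confluent full bank,
    and high-contrast bank subsampled to 176 images before splitting.
    """
    runs = {}
    for seed in STUDY_SEEDS:
        runs[("high", seed)] = run_experiment(ExperimentConfig(seed=seed))
        runs[("low", seed)] = run_experiment(
            ExperimentConfig(regime="low_contrast_confluent", seed=seed))
        runs[("sub176", seed)] = run_experiment(
            ExperimentConfig(subsample_n=176, seed=seed))
    return runs
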
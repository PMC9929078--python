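"""Count-recovery evaluation: MSE, MAE, R² score, Pearson correlation test,
and the bank-size/split ablation table.

Observed counts Y_i and predicted counts Ŷ_i are compared with

* MSE = (1/n) Σ (Y_i − Ŷ_i)²  (count² units)
* MAE = (1/n) Σ |Y_i − Ŷ_i|   (count units)
* R²  = 1 − SS_res / SS_tot   (dimensionless; negative when the model is
  worse than predicting the observed mean; printed as a percentage in tables)
* Pearson r with the two-sided p-value of the exact t transform
  t = r √((n−2)/(1−r²)) against H₀: no correlation, rejected at p < 0.01.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "PredictionSet",
    "EvalReport",
    "mse",
    "mae",
    "r2_score",
    "pearson",
    "evaluate_predictions",
    "ablation_table",
    "correlation_plot",
]


@dataclass(frozen=True)
class PredictionSet:
    """Aligned observed / predicted count vectors for one evaluation bank."""

    observed: np.ndarray
    predicted: np.ndarray
    bank_tag: str = ""

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float).ravel()
        pred = np.asarray(self.predicted, dtype=float).ravel()
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "predicted", pred)
        if obs.shape != pred.shape:
            raise ValidationError(
                f"observed ({obs.shape}) and predicted ({pred.shape}) differ in length")
        if obs.size == 0:
            raise ValidationError("empty prediction set")
        if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
            raise ValidationError("observed/predicted values must be finite")

    @property
    def n(self) -> int:
        return int(self.observed.size)

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.predicted


@dataclass(frozen=True)
class EvalReport:
    """The evaluation battery for one observed/predicted set."""

    mse: float
    mae: float
    r2_score: float             # fraction; multiply by 100 for table display
    pearson_r: float
    p_value: float
    h0_rejected_at_0p01: bool
    n: int
    bank_tag: str = ""

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "r2_score": self.r2_score,
            "r2_percent": 100.0 * self.r2_score,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "h0_rejected_at_0p01": self.h0_rejected_at_0p01,
            "n": self.n,
            "bank_tag": self.bank_tag,
        }


def mse(pred: PredictionSet) -> float:
    """Mean squared residual; zero iff observed == predicted elementwise."""
    return float(np.mean(pred.residuals**2))


def mae(pred: PredictionSet) -> float:
    """Mean absolute residual."""
    return float(np.mean(np.abs(pred.residuals)))


def r2_score(pred: PredictionSet) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot; may be negative."""
    if pred.n < 2:
        raise UndefinedMetricError("R² needs at least 2 pairs")
    ss_tot = float(np.sum((pred.observed - pred.observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R² undefined: observed values are all identical")
    ss_res = float(np.sum(pred.residuals**2))
    return 1.0 - ss_res / ss_tot


def pearson(pred: PredictionSet) -> tuple[float, float]:
    """Sample Pearson r and the two-sided p-value (t distribution, n−2 df)."""
    if pred.n < 3:
        raise UndefinedMetricError("Pearson test needs at least 3 pairs")
    if np.std(pred.observed) == 0.0 or np.std(pred.predicted) == 0.0:
        raise UndefinedMetricError(
            "Pearson r undefined: a series has zero variance "
            f"(observed std {np.std(pred.observed):.3g}, "
            f"predicted std {np.std(pred.predicted):.3g})")
    r, p = stats.pearsonr(pred.observed, pred.predicted)
    return float(r), float(p)


def evaluate_predictions(pred: PredictionSet) -> EvalReport:
    """Compute the full battery for one prediction set."""
    r, p = pearson(pred)
    return EvalReport(
        mse=mse(pred),
        mae=mae(pred),
        r2_score=r2_score(pred),
        pearson_r=r,
        p_value=p,
        h0_rejected_at_0p01=bool(p < 0.01),
        n=pred.n,
        bank_tag=pred.bank_tag,
    )


_ABLATION_ROWS = ["Test", "Training", "Images", "R2 Score", "MAE", "MSE"]


def ablation_table(runs: Sequence[tuple[int, float, EvalReport]]) -> pd.DataFrame:
    """Arrange ablation runs as a table with one column per run.

    Each run is (bank size, train fraction, report); rows are Test %,
    Training %, Images, R² Score (%), MAE, MSE, mirroring how bank-size /
    split ablations are conventionally reported.
    """
    if len(runs) == 0:
        raise ValidationError("ablation_table needs at least one run")
    cols = {}
    for j, (bank_size, train_fraction, report) in enumerate(runs):
        if not np.isfinite(report.mse):
            raise ValidationError(f"run {j} carries a non-finite MSE")
        cols[f"run_{j}"] = [
            f"{round((1 - train_fraction) * 100)}%",
            f"{round(train_fraction * 100)}%",
            bank_size,
            f"{100 * report.r2_score:.2f}%",
            round(report.mae, 2),
            round(report.mse, 2),
        ]
    return pd.DataFrame(cols, index=_ABLATION_ROWS)


def format_ablation(table: pd.DataFrame) -> str:
    """Plain-text rendering of an ablation table."""
    buf = io.StringIO()
    buf.write(table.to_string())
    return buf.getvalue()


def correlation_plot(pred: PredictionSet, path: Optional[str] = None):
    """Scatter of observed vs predicted with marginal histograms and fit line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    ax.scatter(pred.observed, pred.predicted, s=12, alpha=0.6)
    slope, intercept = np.polyfit(pred.observed, pred.predicted, 1)
    xs = np.linspace(pred.observed.min(), pred.observed.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="tab:red", lw=1.5)
    ax.set_xlabel("observed count")
    ax.set_ylabel("predicted count")
    ax_top.hist(pred.observed, bins=20)
    ax_right.hist(pred.predicted, bins=20, orientation="horizontal")
    ax_top.tick_params(labelbottom=False)
    ax_right.tick_params(labelleft=False)
    r, p = pearson(pred)
    ax.set_title(f"R = {r:.3f}, p = {p:.3g}", y=-0.18)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
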
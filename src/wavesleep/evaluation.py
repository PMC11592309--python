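"""Per-class and overall staging metrics, aggregated across CV folds.

Per class i: precision P_i = TP_i/(TP_i+FP_i), recall R_i = TP_i/(TP_i+FN_i),
F1_i their harmonic mean.  Overall: accuracy ACC = trace(cm)/N, macro-F1
MF1 = unweighted mean of the five F1 values, and Cohen's kappa
(p0 − pc)/(1 − pc) with p0 = ACC and pc = Σ_i row_i·col_i / N².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stages import N_STAGES, STAGES


@dataclass
class ConfusionMatrix:
    """5×5 counts; rows = true stage, columns = predicted stage."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_STAGES, N_STAGES):
            raise ValueError("confusion matrix must be 5x5")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    """Per-class P/R/F1 plus ACC, MF1 and kappa for one fold."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float
    kappa: float
    n_epochs: int
    fold_id: int = 0

    def as_dict(self) -> dict:
        d = {
            "fold_id": self.fold_id,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "n_epochs": self.n_epochs,
        }
        for i, name in enumerate(STAGES):
            d[f"precision_{name}"] = float(self.precision[i])
            d[f"recall_{name}"] = float(self.recall[i])
            d[f"f1_{name}"] = float(self.f1[i])
        return d


def confusion(true: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    """Count the 5×5 (true, predicted) pairs."""
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted must have equal length")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=int)
    np.add.at(counts, (true, predicted), 1)
    return ConfusionMatrix(counts=counts)


def metrics(cm: ConfusionMatrix, fold_id: int = 0) -> MetricReport:
    """Compute the metric report of one confusion matrix.

    Precision/recall with an empty denominator are set to 0 (with a
    warning), which lowers MF1 conservatively.
    """
    counts = cm.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if np.any(col == 0) or np.any(row == 0):
        empty = [STAGES[i] for i in range(N_STAGES) if col[i] == 0 or row[i] == 0]
        warnings.warn(f"undefined precision/recall for stages {empty}; set to 0",
                      stacklevel=2)
    acc = float(tp.sum() / n)
    pc = float(np.dot(row, col) / n**2)
    kappa = (acc - pc) / (1.0 - pc) if pc < 1.0 else 1.0
    return MetricReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=acc,
        macro_f1=float(f1.mean()),
        kappa=float(kappa),
        n_epochs=int(n),
        fold_id=fold_id,
    )


@dataclass
class FoldSummary:
    """Across-fold mean ± sample SD per metric plus the pooled matrix."""

    mean: dict[str, float]
    std: dict[str, float]
    pooled: ConfusionMatrix
    reports: list[MetricReport] = field(default_factory=list)


def aggregate_folds(
    reports: list[MetricReport], matrices: list[ConfusionMatrix] | None = None
) -> FoldSummary:
    """Mean and sample standard deviation of ACC/MF1/kappa across folds."""
    if not reports:
        raise ValueError("no fold reports")
    keys = ("accuracy", "macro_f1", "kappa")
    values = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
    mean = {k: float(v.mean()) for k, v in values.items()}
    std = {
        k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in values.items()
    }
    if matrices:
        pooled = ConfusionMatrix(
            counts=np.sum([m.counts for m in matrices], axis=0)
        )
    else:
        pooled = ConfusionMatrix(counts=np.zeros((N_STAGES, N_STAGES), dtype=int))
    return FoldSummary(mean=mean, std=std, pooled=pooled, reports=list(reports))
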
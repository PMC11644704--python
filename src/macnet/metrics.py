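"""Evaluation statistics: accuracy, Cohen's kappa, confusion matrices and
the Wilcoxon signed-rank test for paired model comparisons."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion


def confusion(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Count matrix with true classes as rows, predictions as columns."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = None if n_classes is None else np.arange(n_classes)
    return _sk_confusion(y_true, y_pred, labels=labels)


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions, in percent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return 100.0 * float(np.mean(y_true == y_pred))


def accuracy_from_confusion(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=np.float64)
    return 100.0 * float(np.trace(cm) / cm.sum())


def cohens_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement κ = (P0 − Pe)/(1 − Pe) from a confusion
    matrix; Pe = Σ_k row_k · col_k / N²."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.sum()
    p0 = np.trace(cm) / n
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / (n * n)
    if pe >= 1.0:
        warnings.warn(
            "degenerate confusion matrix (Pe = 1); kappa defined as 0",
            RuntimeWarning,
        )
        return 0.0
    return float((p0 - pe) / (1.0 - pe))


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired scores.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for n ≤ 25 pairs.  All-zero differences yield
    p = 1.0 with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p defined as 1.0",
                      RuntimeWarning)
        return 1.0
    method = "exact" if nonzero.size <= 25 else "auto"
    res = stats.wilcoxon(nonzero, zero_method="wilcox",
                         alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class EvalReport:
    """Cross-validated evaluation output."""

    per_fold: list[tuple[float, float]]          # (ACC %, kappa) per fold
    confusion: np.ndarray                        # summed over test folds
    class_names: tuple[str, ...] = ()
    wilcoxon_p: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @property
    def fold_accs(self) -> np.ndarray:
        return np.array([acc for acc, _ in self.per_fold])

    @property
    def mean_acc(self) -> float:
        return float(self.fold_accs.mean())

    @property
    def sd_acc(self) -> float:
        return float(self.fold_accs.std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(np.mean([k for _, k in self.per_fold]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(len(self.per_fold)),
                "acc_percent": [a for a, _ in self.per_fold],
                "kappa": [k for _, k in self.per_fold],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_fold": [[float(a), float(k)] for a, k in self.per_fold],
                "mean_acc": self.mean_acc,
                "sd_acc": self.sd_acc,
                "mean_kappa": self.mean_kappa,
                "confusion": self.confusion.tolist(),
                "class_names": list(self.class_names),
                "wilcoxon_p": self.wilcoxon_p,
                "extra": self.extra,
            },
            indent=2,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
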
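"""Model-accuracy measures: AUC and the Brier score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import UndefinedResultError


@dataclass
class AccuracyReport:
    model: str
    auc: float
    brier: float
    n: int

    def as_dict(self) -> dict:
        return {"model": self.model, "auc": float(self.auc),
                "brier": float(self.brier), "n": int(self.n)}


def auc(y, p) -> float:
    """Rank-based area under the ROC curve (midranks for tied scores)."""
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedResultError("AUC undefined: only one class present")
    return float(roc_auc_score(y, p))


def brier(y, p) -> float:
    """Mean squared difference between the response and predicted probability."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(y) != len(p):
        raise ValueError("length mismatch")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((y - p) ** 2))


def accuracy_report(model: str, y, p) -> AccuracyReport:
    return AccuracyReport(model=model, auc=auc(y, p), brier=brier(y, p), n=len(np.asarray(y)))
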
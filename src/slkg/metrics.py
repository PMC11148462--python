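"""Ranking metrics for pair scoring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class Metrics:
    """AUC-ROC (midrank tie convention) and AUPR (step-wise integration)."""

    auc_roc: float
    aupr: float
    n_pairs: int

    def as_dict(self) -> dict:
        return {"auc_roc": self.auc_roc, "aupr": self.aupr,
                "n_pairs": self.n_pairs}


def compute_metrics(labels: np.ndarray, scores: np.ndarray) -> Metrics:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics require both classes to be present")
    return Metrics(
        auc_roc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        n_pairs=int(len(labels)))
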
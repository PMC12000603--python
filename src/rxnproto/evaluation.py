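"""Classification metrics and repeated-run aggregation.

AUPRC is average precision (the step-function integral of the
precision-recall curve, no interpolation), which is the convention that
makes a random or constant scorer's AUPRC equal the positive-class
prevalence.  AUROC is the probability that a random positive outranks a
random negative, ties counted half.  Both are computed with scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


def _check(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores have different lengths")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute the metric")
    return labels, scores


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    labels, scores = _check(labels, scores)
    return float(average_precision_score(labels, scores))


def auroc(labels, scores) -> float:
    """Area under the ROC curve (rank statistic with half-tie credit)."""
    labels, scores = _check(labels, scores)
    return float(roc_auc_score(labels, scores))


def aggregate(runs) -> tuple[float, float | None]:
    """Mean and standard error (sample sd / sqrt(n)) over repeated runs.

    With a single run the standard error is undefined and returned as None.
    """
    runs = np.asarray(list(runs), dtype=float)
    if runs.size == 0:
        raise ValueError("no runs to aggregate")
    mean = float(runs.mean())
    if runs.size < 2:
        return mean, None
    return mean, float(runs.std(ddof=1) / np.sqrt(runs.size))


@dataclass
class EvalReport:
    """Per-protocol evaluation summary over repeated support/query splits."""

    method: str
    protocol: str
    support_size: int | str
    threshold: float
    auprc_runs: list[float] = field(default_factory=list)
    auroc_runs: list[float] = field(default_factory=list)
    manifests: list[dict] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.auprc_runs)

    def summary(self) -> dict:
        ap_mean, ap_se = aggregate(self.auprc_runs)
        roc_mean, roc_se = aggregate(self.auroc_runs)
        return {
            "method": self.method,
            "protocol": self.protocol,
            "support_size": self.support_size,
            "threshold": self.threshold,
            "n_runs": self.n_runs,
            "auprc_mean": ap_mean,
            "auprc_stderr": ap_se,
            "auroc_mean": roc_mean,
            "auroc_stderr": roc_se,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"summary": self.summary(),
                       "auprc_runs": self.auprc_runs,
                       "auroc_runs": self.auroc_runs,
                       "manifests": self.manifests}, fh, indent=1)


def reports_to_frame(reports: list[EvalReport]):
    """Flat table (one row per method x protocol x support size)."""
    import pandas as pd
    return pd.DataFrame([r.summary() for r in reports])
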
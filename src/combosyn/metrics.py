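"""Evaluation metrics for the synergy classifier.

AUC is computed as the Mann–Whitney concordance probability (ties credited
0.5) via midranks, and AUPR as the step-interpolated area under the
precision–recall curve (precision at each threshold weighted by the recall
increment). Both match their brute-force definitions exactly, which the
test suite verifies pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, rankdata

__all__ = ["auc_score", "aupr_score", "accuracy_score", "metric_suite", "EvalReport"]


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC/AUPR need at least one positive and one negative")
    return n_pos, n_neg


def auc_score(scores, labels) -> float:
    """Mann–Whitney concordance: P(score_pos > score_neg) + 0.5·P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos, n_neg = _check_two_class(labels)
    ranks = rankdata(scores)  # midranks handle ties with 0.5 credit
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr_score(scores, labels) -> float:
    """Step-interpolated area under precision–recall (average precision)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos, _ = _check_two_class(labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at distinct thresholds (last index of each tied block)
    distinct = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * drecall))


def accuracy_score(scores, labels, threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    return float(((scores >= threshold).astype(int) == labels).mean())


@dataclass
class EvalReport:
    """Aggregate metrics with per-fold breakdown (mean ± sd presentation)."""

    auc: float
    aupr: float
    acc: float
    pcc: float = float("nan")
    rmse: float = float("nan")
    per_fold: list[dict] = field(default_factory=list)
    n_folds: int = 1
    ablation: dict | None = None

    def summary(self) -> str:
        lines = [f"{'metric':<8}{'mean':>10}{'sd':>10}"]
        for name in ("auc", "aupr", "acc", "pcc", "rmse"):
            vals = [f[name] for f in self.per_fold if name in f] or [getattr(self, name)]
            vals = [v for v in vals if np.isfinite(v)]
            if not vals:
                continue
            lines.append(f"{name:<8}{np.mean(vals):>10.4f}{np.std(vals):>10.4f}")
        return "\n".join(lines)


def metric_suite(
    pred_scores,
    labels,
    pred_values=None,
    true_values=None,
    threshold: float = 0.5,
) -> dict:
    """Classification metrics, plus PCC/RMSE when continuous predictions given."""
    out = {
        "auc": auc_score(pred_scores, labels),
        "aupr": aupr_score(pred_scores, labels),
        "acc": accuracy_score(pred_scores, labels, threshold),
    }
    if pred_values is not None and true_values is not None:
        pred_values = np.asarray(pred_values, dtype=np.float64)
        true_values = np.asarray(true_values, dtype=np.float64)
        out["rmse"] = float(np.sqrt(np.mean((pred_values - true_values) ** 2)))
        if np.std(pred_values) == 0 or np.std(true_values) == 0:
            out["pcc"] = float("nan")
        else:
            out["pcc"] = float(pearsonr(pred_values, true_values)[0])
    return out
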
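"""Evaluation metrics: AUROC, AUPRC, precision/recall, Top-k recovery, PRCE.

AUROC is the Mann-Whitney pair statistic (ties count one half); AUPRC is the
step-wise precision-recall integral (average precision).  Both delegate to
scikit-learn, which implements exactly those estimators.  Top-k recovery is
a per-protein ranked metric: among proteins with at least one positive site,
the fraction whose k highest-scored sites contain a true positive.  PRCE is
the AUPRC enrichment over the random-classifier baseline (the positive
fraction): 100 * (AUPRC - f_pos) / f_pos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import CysligandError, DegenerateDataError

Site = tuple[str, int]

TP, TN, FP, FN = "TP", "TN", "FP", "FN"


@dataclass
class PredictionSet:
    """Per-site ensemble-mean scores in [0, 1] with protein grouping."""

    scores: dict[Site, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for site, s in self.scores.items():
            if not np.isfinite(s) or not 0.0 <= s <= 1.0:
                raise CysligandError(f"score {s} for {site} outside [0, 1]")

    def proteins(self) -> dict[str, list[Site]]:
        out: dict[str, list[Site]] = {}
        for site in sorted(self.scores):
            out.setdefault(site[0], []).append(site)
        return out

    def array_for(self, sites: list[Site]) -> np.ndarray:
        return np.asarray([self.scores[s] for s in sites])


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("metric undefined for single-class labels")


def auroc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def precision_recall_at(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """Precision and recall of the positive class at score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall


def prce(auprc_value: float, positive_fraction: float) -> float:
    """AUPRC enrichment over a random classifier, as a percentage."""
    if not 0.0 < positive_fraction < 1.0:
        raise CysligandError("positive_fraction must lie strictly in (0, 1)")
    return float(100.0 * (auprc_value - positive_fraction) / positive_fraction)


def top_k_recovery(predictions: PredictionSet, labels: dict[Site, int],
                   k: int = 1) -> float:
    """Fraction of positive-bearing proteins whose top-k sites hit a positive.

    Proteins without any positive site are excluded from the denominator.
    Score ties break deterministically by (uid, position).
    """
    if k < 1:
        raise CysligandError("k must be >= 1")
    n_eligible = 0
    n_hit = 0
    for uid, sites in predictions.proteins().items():
        pos_sites = [s for s in sites if labels.get(s, 0) == 1]
        if not pos_sites:
            continue
        n_eligible += 1
        ranked = sorted(sites, key=lambda s: (-predictions.scores[s], s))
        if any(labels.get(s, 0) == 1 for s in ranked[:k]):
            n_hit += 1
    if n_eligible == 0:
        raise DegenerateDataError("no protein has a positive site")
    return n_hit / n_eligible


def confusion_classes(predictions: PredictionSet, labels: dict[Site, int],
                      threshold: float = 0.5) -> dict[Site, str]:
    """Per-site TP/TN/FP/FN at the threshold (score >= threshold is positive)."""
    if not 0.0 < threshold < 1.0:
        raise CysligandError("threshold must lie in (0, 1)")
    out: dict[Site, str] = {}
    for site, score in predictions.scores.items():
        pred_pos = score >= threshold
        truth_pos = labels[site] == 1
        out[site] = (TP if truth_pos else FP) if pred_pos else (FN if truth_pos else TN)
    return out


@dataclass
class MetricReport:
    auroc: float
    auprc: float
    precision: float
    recall: float
    prce: float
    top_k: dict[int, float]
    aggregation: str  # "pooled" | "per-protein"
    n_pos: int
    n_neg: int
    n_proteins: int

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc, "auprc": self.auprc,
            "precision": self.precision, "recall": self.recall,
            "prce": self.prce,
            "top_k": {str(k): v for k, v in self.top_k.items()},
            "aggregation": self.aggregation,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "n_proteins": self.n_proteins,
        }


def evaluate(predictions: PredictionSet, labels: dict[Site, int],
             ks: tuple[int, ...] = (1,), aggregation: str = "pooled",
             threshold: float = 0.5) -> MetricReport:
    """Full metric report over the labeled sites of a prediction set.

    ``aggregation='pooled'`` computes AUROC/AUPRC over all sites at once;
    ``'per-protein'`` averages per-protein values over proteins where the
    metric is defined (both classes present).  Top-k is always per-protein.
    """
    sites = sorted(s for s in predictions.scores if s in labels)
    y = np.asarray([labels[s] for s in sites], dtype=int)
    x = predictions.array_for(sites)
    if aggregation == "pooled":
        roc, prc = auroc(x, y), auprc(x, y)
    elif aggregation == "per-protein":
        rocs, prcs = [], []
        for uid, psites in predictions.proteins().items():
            psites = [s for s in psites if s in labels]
            py = np.asarray([labels[s] for s in psites], dtype=int)
            if len(np.unique(py)) < 2:
                continue
            px = predictions.array_for(psites)
            rocs.append(auroc(px, py))
            prcs.append(auprc(px, py))
        if not rocs:
            raise DegenerateDataError("no protein has both classes")
        roc, prc = float(np.mean(rocs)), float(np.mean(prcs))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    precision, recall = precision_recall_at(x, y, threshold)
    f_pos = float(np.mean(y))
    sub = PredictionSet({s: predictions.scores[s] for s in sites})
    return MetricReport(
        auroc=roc, auprc=prc, precision=precision, recall=recall,
        prce=prce(prc, f_pos) if 0 < f_pos < 1 else float("nan"),
        top_k={k: top_k_recovery(sub, labels, k) for k in ks},
        aggregation=aggregation,
        n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()),
        n_proteins=len({s[0] for s in sites}),
    )


__all__ = [
    "TP", "TN", "FP", "FN", "PredictionSet", "MetricReport",
    "auroc", "auprc", "precision_recall_at", "prce",
    "top_k_recovery", "confusion_classes", "evaluate",
]
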
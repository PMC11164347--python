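"""Evaluation metrics for multi-label prediction sets.

Sample-averaged metrics score each protein's set against its ground truth and
average over proteins; micro-averaged metrics pool every (protein, label)
decision before computing precision/recall. Empty prediction sets contribute
precision 0 (and FDR 0, by the empty-set convention), so coverage — the
fraction of proteins receiving at least one prediction — is always reported
alongside to make the effect visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import precision_recall_curve

from .conformal import ScoreMatrix, prediction_set
from .ontology import AnnotationSet, ECNumber

__all__ = [
    "EvalReport",
    "sample_prf",
    "realized_fdr",
    "micro_pr_curve",
    "ndcg",
    "mean_ndcg",
    "coverage",
    "fdr_at_first_hit",
    "evaluate_at_lambda",
]


@dataclass
class EvalReport:
    """Per-tolerance evaluation records plus per-protein first-hit values."""

    records: List[Dict[str, float]] = field(default_factory=list)
    fdr_at_first_hit: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "fdr_at_first_hit": self.fdr_at_first_hit,
        }


def _aligned_truth(preds_proteins: Sequence[str], truth: AnnotationSet):
    return [truth[pid] for pid in preds_proteins]


def sample_prf(
    preds: Sequence[Set[ECNumber]], truths: Sequence[Set[ECNumber]]
) -> Tuple[float, float, float]:
    """Sample-averaged precision, recall and F1.

    Per protein: precision |C & Y| / |C| (0 for empty C), recall
    |C & Y| / |Y|, F1 the harmonic mean (0 when P + R = 0); each averaged
    over proteins.
    """
    if len(preds) != len(truths):
        raise ValueError("predictions and truths must align")
    if not preds:
        raise ValueError("no proteins to evaluate")
    ps, rs, fs = [], [], []
    for c, y in zip(preds, truths):
        if not y:
            raise ValueError("ground-truth label set must be non-empty")
        tp = len(c & y)
        p = tp / len(c) if c else 0.0
        r = tp / len(y)
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(f)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def realized_fdr(
    preds: Sequence[Set[ECNumber]], truths: Sequence[Set[ECNumber]]
) -> float:
    """Mean per-protein false discovery proportion (empty sets count 0)."""
    losses = []
    for c, y in zip(preds, truths):
        losses.append(0.0 if not c else 1.0 - len(c & y) / len(c))
    return float(np.mean(losses))


def coverage(preds: Sequence[Set[ECNumber]]) -> float:
    """Fraction of proteins with a non-empty prediction set."""
    if not preds:
        raise ValueError("no proteins to evaluate")
    return float(np.mean([bool(c) for c in preds]))


def micro_pr_curve(
    scores: ScoreMatrix, truth: AnnotationSet
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Micro-averaged precision-recall curve over pooled (protein, label)
    pairs, plus Fmax, the maximum micro-F1 along the curve.

    Returns ``(thresholds, precision, recall, fmax)`` where precision and
    recall have one more entry than thresholds (the conventional curve
    endpoint at recall 0).
    """
    mask = truth.subset(scores.proteins).indicator_matrix(scores.labels)
    y_true = mask.ravel()
    y_score = scores.scores.ravel()
    precision, recall, thresholds = precision_recall_curve(y_true, y_score)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    f1 = np.nan_to_num(f1)
    fmax = float(f1.max())
    return thresholds, precision, recall, fmax


def ndcg(
    scores_row: np.ndarray,
    labels: Sequence[ECNumber],
    pred: Set[ECNumber],
    truth: Set[ECNumber],
) -> float:
    """Normalized discounted cumulative gain of a prediction set.

    The predicted labels are ranked by descending score (ties broken by
    label order); binary relevance with 1 / log2(rank + 1) discounting. The
    ideal ranking places every true label first, so false negatives lower
    the score even when all predictions are correct. Empty prediction sets
    score 0.
    """
    if not truth:
        raise ValueError("ground-truth label set must be non-empty")
    if not pred:
        return 0.0
    scores_row = np.asarray(scores_row, dtype=float)
    col = {ec: j for j, ec in enumerate(labels)}
    members = sorted(pred, key=lambda ec: (-scores_row[col[ec]], ec))
    dcg = sum(
        1.0 / np.log2(rank + 2)
        for rank, ec in enumerate(members)
        if ec in truth
    )
    idcg = sum(1.0 / np.log2(rank + 2) for rank in range(len(truth)))
    return float(dcg / idcg)


def mean_ndcg(
    scores: ScoreMatrix, preds: Sequence[Set[ECNumber]], truth: AnnotationSet
) -> float:
    """nDCG averaged over proteins."""
    vals = [
        ndcg(scores.scores[i], scores.labels, preds[i], truth[pid])
        for i, pid in enumerate(scores.proteins)
    ]
    return float(np.mean(vals))


def evaluate_at_lambda(
    scores: ScoreMatrix, truth: AnnotationSet, lam: float
) -> Dict[str, float]:
    """All set-level metrics of the lam-thresholded predictions."""
    preds = [
        prediction_set(scores.scores[i], scores.labels, lam)
        for i in range(len(scores))
    ]
    truths = _aligned_truth(scores.proteins, truth)
    p, r, f = sample_prf(preds, truths)
    return {
        "lambda": float(lam),
        "fdr": realized_fdr(preds, truths),
        "precision": p,
        "recall": r,
        "f1": f,
        "ndcg": mean_ndcg(scores, preds, truth),
        "coverage": coverage(preds),
    }


def fdr_at_first_hit(
    scores: ScoreMatrix,
    truth: AnnotationSet,
    calibrations: Dict[float, float],
) -> Dict[str, float]:
    """Smallest tolerance alpha at which each protein's set first contains a
    true label.

    ``calibrations`` maps alpha -> calibrated threshold lambda (``inf`` for
    abstention). Because thresholds are non-increasing in alpha, prediction
    sets are nested and a hit, once gained, persists. Proteins never hit on
    the alpha grid are reported as ``nan``.
    """
    alphas = sorted(calibrations)
    mask = truth.subset(scores.proteins).indicator_matrix(scores.labels)
    out: Dict[str, float] = {}
    for i, pid in enumerate(scores.proteins):
        true_scores = scores.scores[i][mask[i]]
        best = np.nan
        for a in alphas:
            lam = calibrations[a]
            if np.isfinite(lam) and (true_scores >= lam).any():
                best = a
                break
        out[pid] = best
    return out
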
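"""Adaptive coarse/fine EC prediction: level-4 sets with level-3 fallback.

A model should not emit a more specific EC number than its confidence
supports. The cascade first forms the calibrated level-4 prediction set; if
it is empty (the fine-level tolerance could not be met for this protein), it
falls back to the calibrated level-3 set; if that is empty too, the protein
is left uncalled. Both levels are calibrated independently, by default at
the same FDR tolerance alpha.

Level-3 ground truth is derived by truncating the level-4 annotations and
deduplicating. Level-3 scores may be supplied by a separately calibrated
coarse model, or derived from the level-4 score matrix by max-pooling over
each level-3 prefix's children (a level-3 claim is as plausible as its most
plausible level-4 refinement).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence, Set

import numpy as np

from .conformal import ScoreMatrix, prediction_set
from .ontology import AnnotationSet, ECNumber

__all__ = [
    "CascadeCategory",
    "CascadeOutcome",
    "cascade_predict",
    "cascade_predict_all",
    "hit_rate",
    "pool_scores_to_level",
]


class CascadeCategory(str, Enum):
    HIT4 = "HIT4"  # fine set emitted and contains a true level-4 label
    HIT3 = "HIT3"  # fell back; coarse set contains a true level-3 label
    INCORRECT_BOTH = "INCORRECT_BOTH"  # something emitted, nothing correct
    NOT_CALLED = "NOT_CALLED"  # both levels empty


@dataclass
class CascadeOutcome:
    protein: str
    category: CascadeCategory
    emitted_set: Set[ECNumber]
    emitted_level: int | None  # 4, 3, or None when nothing was emitted


def pool_scores_to_level(scores: ScoreMatrix, level: int = 3) -> ScoreMatrix:
    """Max-pool a level-4 score matrix over each coarse prefix's children."""
    if not 1 <= level <= 3:
        raise ValueError("pooling level must be in 1..3")
    groups: Dict[ECNumber, List[int]] = {}
    for j, ec in enumerate(scores.labels):
        groups.setdefault(ec.truncate(min(level, ec.level)), []).append(j)
    coarse = sorted(groups)
    pooled = np.stack(
        [scores.scores[:, groups[ec]].max(axis=1) for ec in coarse], axis=1
    )
    return ScoreMatrix(list(scores.proteins), coarse, pooled)


def _classify(
    pid: str,
    set4: Set[ECNumber],
    set3: Set[ECNumber],
    truth4: Set[ECNumber],
) -> CascadeOutcome:
    truth3 = {ec.truncate(3) for ec in truth4}
    if set4:
        if set4 & truth4:
            cat = CascadeCategory.HIT4
        else:
            cat = CascadeCategory.INCORRECT_BOTH
        return CascadeOutcome(pid, cat, set4, 4)
    if set3:
        if set3 & truth3:
            cat = CascadeCategory.HIT3
        else:
            cat = CascadeCategory.INCORRECT_BOTH
        return CascadeOutcome(pid, cat, set3, 3)
    return CascadeOutcome(pid, CascadeCategory.NOT_CALLED, set(), None)


def cascade_predict(
    scores4: np.ndarray,
    labels4: Sequence[ECNumber],
    lam4: float,
    scores3: np.ndarray,
    labels3: Sequence[ECNumber],
    lam3: float,
    protein: str = "",
    truth4: Set[ECNumber] | None = None,
) -> CascadeOutcome:
    """Cascade prediction for one protein row.

    Emits the level-4 set when non-empty, else the level-3 set, else nothing.
    When ``truth4`` is given the outcome is categorised against it; otherwise
    the category is NOT_CALLED/placeholder-free and only the emitted set and
    level are meaningful.
    """
    if any(ec.level != 4 for ec in labels4):
        raise ValueError("fine universe must contain level-4 codes")
    if any(ec.level != 3 for ec in labels3):
        raise ValueError("coarse universe must contain level-3 codes")
    set4 = prediction_set(scores4, list(labels4), lam4)
    set3 = prediction_set(scores3, list(labels3), lam3)
    if truth4 is None:
        if set4:
            return CascadeOutcome(protein, CascadeCategory.NOT_CALLED, set4, 4)
        if set3:
            return CascadeOutcome(protein, CascadeCategory.NOT_CALLED, set3, 3)
        return CascadeOutcome(protein, CascadeCategory.NOT_CALLED, set(), None)
    return _classify(protein, set4, set3, truth4)


def cascade_predict_all(
    scores4: ScoreMatrix,
    lam4: float,
    scores3: ScoreMatrix,
    lam3: float,
    truth: AnnotationSet,
) -> List[CascadeOutcome]:
    """Cascade outcomes for every protein in the score matrices."""
    if scores4.proteins != scores3.proteins:
        raise ValueError("fine and coarse score matrices must share proteins")
    out = []
    for i, pid in enumerate(scores4.proteins):
        out.append(
            cascade_predict(
                scores4.scores[i],
                scores4.labels,
                lam4,
                scores3.scores[i],
                scores3.labels,
                lam3,
                protein=pid,
                truth4=truth[pid],
            )
        )
    return out


def hit_rate(outcomes: Sequence[CascadeOutcome]) -> Dict[str, float]:
    """Fractions of HIT4 / HIT3 / INCORRECT_BOTH / NOT_CALLED outcomes.

    The four fractions partition the proteins and sum to 1.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarise")
    n = len(outcomes)
    counts = {cat.value: 0 for cat in CascadeCategory}
    for o in outcomes:
        counts[o.category.value] += 1
    return {k: v / n for k, v in counts.items()}
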
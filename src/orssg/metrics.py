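"""Evaluation protocol: per-class and macro precision / recall / F1.

Relation scoring compares, for every ordered pair of ground-truth entities
in every frame, the predicted relation label (background if no edge) with
the ground-truth label, accumulating a 15-class confusion matrix.  Role and
phase scoring reuse the same confusion machinery over 5 and 8 classes.
Macro averages are unweighted means over classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .core import NONE_RELATION, RelationVocabulary, SceneGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ClassScores",
    "harmonic_f1",
    "macro_average",
    "prf_from_labels",
    "relation_prf",
    "relation_pair_labels",
]


@dataclass(frozen=True)
class PerClass:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class ClassScores:
    per_class: dict[Hashable, PerClass]
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def rounded(self, digits: int = 2) -> dict:
        """Report at print precision; full precision is kept internally."""
        return {
            "per_class": {
                str(k): {
                    "precision": round(v.precision, digits),
                    "recall": round(v.recall, digits),
                    "f1": round(v.f1, digits),
                    "support": v.support,
                }
                for k, v in self.per_class.items()
            },
            "macro": {
                "precision": round(self.macro_precision, digits),
                "recall": round(self.macro_recall, digits),
                "f1": round(self.macro_f1, digits),
            },
        }


def harmonic_f1(precision: float, recall: float) -> float:
    """2pr/(p+r), defined as 0 at p = r = 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_average(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean over classes (no support weighting)."""
    if len(values) == 0:
        raise ValueError("macro average of an empty list")
    return float(np.mean(values))


def prf_from_labels(
    y_true: Sequence[Hashable],
    y_pred: Sequence[Hashable],
    classes: Sequence[Hashable],
) -> ClassScores:
    """Confusion-matrix P/R/F1 for a fixed class list (all classes scored,
    present or not)."""
    if len(y_true) != len(y_pred):
        raise ValueError("label lists must align")
    index = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    confusion = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    per_class: dict[Hashable, PerClass] = {}
    for c, i in index.items():
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        per_class[c] = PerClass(
            float(precision), float(recall), harmonic_f1(precision, recall), int(tp + fn)
        )
    return ClassScores(
        per_class=per_class,
        macro_precision=macro_average([v.precision for v in per_class.values()]),
        macro_recall=macro_average([v.recall for v in per_class.values()]),
        macro_f1=macro_average([v.f1 for v in per_class.values()]),
    )


def relation_pair_labels(
    predicted: Sequence[SceneGraph],
    ground_truth: Sequence[SceneGraph],
) -> tuple[list[str], list[str]]:
    """Flatten frame-aligned graph sequences to per-pair label lists.

    The pair universe is every ordered pair of ground-truth entities; a
    relation counts only if both entities are present in the scene, so
    predicted edges on hallucinated entities are ignored (logged).
    """
    if len(predicted) != len(ground_truth):
        raise ValueError("predicted and ground-truth sequences must be frame-aligned")
    y_true: list[str] = []
    y_pred: list[str] = []
    for pred, gt in zip(predicted, ground_truth):
        if pred.frame_id != gt.frame_id:
            raise ValueError(
                f"frame misalignment: predicted {pred.frame_id} vs gt {gt.frame_id}"
            )
        gt_ids = sorted(gt.nodes)
        hallucinated = set(pred.nodes) - set(gt.nodes)
        for subj, rel, obj in pred.edges:
            if subj in hallucinated or obj in hallucinated:
                logger.debug(
                    "frame %d: ignoring edge on hallucinated entity (%s, %s, %s)",
                    pred.frame_id, subj, rel, obj,
                )
        for a in gt_ids:
            for b in gt_ids:
                if a == b:
                    continue
                y_true.append(gt.relation_between(a, b) or NONE_RELATION)
                if a in pred.nodes and b in pred.nodes:
                    y_pred.append(pred.relation_between(a, b) or NONE_RELATION)
                else:
                    y_pred.append(NONE_RELATION)
    return y_true, y_pred


def relation_prf(
    predicted: Sequence[SceneGraph],
    ground_truth: Sequence[SceneGraph],
    relations: RelationVocabulary | None = None,
    include_none: bool = True,
) -> ClassScores:
    """The 15-class relation protocol (background class included by default)."""
    relations = relations or RelationVocabulary()
    y_true, y_pred = relation_pair_labels(predicted, ground_truth)
    classes = list(relations.names) if include_none else list(relations.semantic)
    if not include_none:
        kept = [(t, p) for t, p in zip(y_true, y_pred) if t != NONE_RELATION]
        y_true = [t for t, _ in kept]
        y_pred = [p if p != NONE_RELATION else NONE_RELATION for _, p in kept]
        # background predictions on semantic pairs count as misses: map them
        # to a class outside the list by scoring via confusion on full list
        classes_full = list(relations.names)
        scores_full = prf_from_labels(y_true, y_pred, classes_full)
        per_class = {c: scores_full.per_class[c] for c in classes}
        return ClassScores(
            per_class=per_class,
            macro_precision=macro_average([v.precision for v in per_class.values()]),
            macro_recall=macro_average([v.recall for v in per_class.values()]),
            macro_f1=macro_average([v.f1 for v in per_class.values()]),
        )
    return prf_from_labels(y_true, y_pred, classes)
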
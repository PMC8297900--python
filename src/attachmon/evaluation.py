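"""Leave-One-Child-Out evaluation and classification metrics.

The automatic rater is validated with one cross-validation fold per child:
the model is trained on every other child's windows and tested on the
held-out child, so a child's own windows never inform its rating.  Metrics
are computed at two levels: per child (after the majority vote, the level
at which ratings are used) and per window (diagnostic).  The positive
class for precision and recall is *insecure* — the class a screening
instrument must not miss.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifier import (
    ChildRating,
    Model,
    ModelSpec,
    WindowPrediction,
    majority_vote,
    predict_windows,
    train,
)
from .errors import DegenerateInputError, ProtocolError
from .kinematics import FeatureWindow
from .labels import BinaryLabel

__all__ = [
    "ConfusionMatrix2",
    "ClassificationMetrics",
    "LocoResult",
    "compute_metrics",
    "loco_evaluate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix2:
    """Binary confusion counts; positive class = insecure."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy (alpha), precision (pi), recall (rho) and F1."""

    alpha: float
    pi: float
    rho: float
    f1: float


def compute_metrics(cm: ConfusionMatrix2) -> ClassificationMetrics:
    """Accuracy, precision, recall and F1 from binary confusion counts.

    Ratios with a zero denominator are reported as NaN with a warning,
    never silently as 0.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    alpha = (cm.tp + cm.tn) / cm.n

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning)
            return float("nan")
        return num / den

    pi = ratio(cm.tp, cm.tp + cm.fp, "precision")
    rho = ratio(cm.tp, cm.tp + cm.fn, "recall")
    if np.isnan(pi) or np.isnan(rho) or pi + rho == 0:
        if pi + rho == 0 and not (np.isnan(pi) or np.isnan(rho)):
            warnings.warn("F1 undefined (precision + recall = 0)", RuntimeWarning)
        f1 = float("nan")
    else:
        f1 = 2.0 * pi * rho / (pi + rho)
    return ClassificationMetrics(alpha=alpha, pi=pi, rho=rho, f1=f1)


@dataclass(frozen=True)
class LocoResult:
    """Outcome of a Leave-One-Child-Out run."""

    per_child: tuple[tuple[str, BinaryLabel, ChildRating], ...]
    child_level_metrics: ClassificationMetrics
    window_level_metrics: ClassificationMetrics
    child_confusion: ConfusionMatrix2
    window_confusion: ConfusionMatrix2
    n_folds: int


def _confusion(pairs: Sequence[tuple[BinaryLabel, BinaryLabel]]) -> ConfusionMatrix2:
    tp = fp = fn = tn = 0
    for truth, pred in pairs:
        if truth is BinaryLabel.INSECURE:
            if pred is BinaryLabel.INSECURE:
                tp += 1
            else:
                fn += 1
        else:
            if pred is BinaryLabel.INSECURE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix2(tp=tp, fp=fp, fn=fn, tn=tn)


def loco_evaluate(
    windows_by_child: Mapping[str, Sequence[FeatureWindow]],
    spec: ModelSpec,
) -> LocoResult:
    """Run the Leave-One-Child-Out protocol over a labelled dataset.

    One fold per child; per-fold training uses ``spec.seed + fold_index``
    so runs are reproducible yet folds are not identically initialised.
    Children with zero windows are excluded with a logged warning.
    """
    children = [cid for cid in windows_by_child if len(windows_by_child[cid]) > 0]
    for cid in windows_by_child:
        if cid not in children:
            logger.warning("child %s has no windows; excluded from LOCO", cid)
    if len(children) < 2:
        raise ProtocolError("LOCO needs at least 2 children with windows")

    truth: dict[str, BinaryLabel] = {}
    for cid in children:
        label = windows_by_child[cid][0].label
        if label is None:
            raise ValueError(f"child {cid} has unlabelled windows")
        truth[cid] = label.binary()
    if len({v for v in truth.values()}) < 2:
        raise DegenerateInputError("all children share one class; LOCO degenerate")

    per_child = []
    window_pairs: list[tuple[BinaryLabel, BinaryLabel]] = []
    for fold, test_id in enumerate(children):
        train_windows = [
            w for cid in children if cid != test_id for w in windows_by_child[cid]
        ]
        assert not {w.child_id for w in train_windows} & {test_id}, "fold leakage"
        fold_spec = ModelSpec(
            backend=spec.backend,
            hidden_size=spec.hidden_size,
            epochs=spec.epochs,
            learning_rate=spec.learning_rate,
            class_weighting=spec.class_weighting,
            seed=spec.seed + fold,
            max_windows_per_child=spec.max_windows_per_child,
        )
        fold_classes = {w.label.binary() for w in train_windows}
        if len(fold_classes) == 1:
            # minimal-protocol degenerate fold (e.g. 2 children, one per
            # class): the only consistent prediction is the training class
            only = fold_classes.pop()
            logger.warning(
                "fold %d: single-class training set; constant prediction %s",
                fold,
                only.value,
            )
            p = 1.0 if only is BinaryLabel.INSECURE else 0.0
            preds = [
                WindowPrediction(w.child_id, w.window_index, p, only)
                for w in windows_by_child[test_id]
            ]
        else:
            model = train(train_windows, fold_spec)
            preds = predict_windows(model, list(windows_by_child[test_id]))
        rating = majority_vote(preds, cap=spec.max_windows_per_child)
        per_child.append((test_id, truth[test_id], rating))
        capped = sorted(preds, key=lambda p: p.window_index)
        if spec.max_windows_per_child is not None:
            capped = capped[: spec.max_windows_per_child]
        window_pairs.extend((truth[test_id], p.hard_label) for p in capped)
        logger.info(
            "fold %d/%d: child %s, %d train windows, rated %s (truth %s)",
            fold + 1,
            len(children),
            test_id,
            len(train_windows),
            rating.label.value,
            truth[test_id].value,
        )

    child_cm = _confusion([(t, r.label) for _, t, r in per_child])
    window_cm = _confusion(window_pairs)
    return LocoResult(
        per_child=tuple(per_child),
        child_level_metrics=compute_metrics(child_cm),
        window_level_metrics=compute_metrics(window_cm),
        child_confusion=child_cm,
        window_confusion=window_cm,
        n_folds=len(children),
    )
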
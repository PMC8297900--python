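"""Window-level secure/insecure classification and per-child majority vote.

Each 128-frame feature window is classified independently as coming from a
secure or an insecure child; window labels are inherited from the child's
manual coding (secure = B, insecure = A/C/D — no window-level ground truth
exists).  A child's rating is the modal window decision over at most
``max_windows_per_child`` windows in temporal order, ties resolving to
insecure (a screening instrument prefers sensitivity; configurable).

Two interchangeable backends:

* ``recurrent-sequence`` — a small gated recurrent network over the raw
  per-frame feature sequence (the reference model for sequential data);
* ``summary-logistic`` — logistic regression on per-window summary
  statistics (means and standard deviations of the continuous channels
  plus the presence proportions); fast and fully deterministic.

Both consume z-scored features (the scaler is fitted on the training
windows and stored with the model) and support inverse-frequency class
weighting for the expected ~70/30 secure/insecure imbalance.  Models
serialise to a single JSON file embedding the spec and a feature-schema
hash; prediction refuses windows with a mismatched schema.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from ._rnn import GRUClassifier
from .errors import DegenerateInputError, SchemaError
from .kinematics import (
    CONTINUOUS_COLUMNS,
    FEATURE_COLUMNS,
    FeatureWindow,
    feature_schema_hash,
)
from .labels import BinaryLabel

__all__ = [
    "ModelSpec",
    "Model",
    "WindowPrediction",
    "ChildRating",
    "train",
    "predict_windows",
    "majority_vote",
    "save_model",
    "load_model",
]

BACKENDS = ("recurrent-sequence", "summary-logistic")


@dataclass(frozen=True)
class ModelSpec:
    """Training configuration; seeded training is deterministic."""

    backend: str = "summary-logistic"
    hidden_size: int = 16
    epochs: int = 60
    learning_rate: float = 0.02
    class_weighting: str = "balanced"  # or "none"
    seed: int = 0
    max_windows_per_child: int | None = 500  # None = unlimited

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError("class_weighting must be 'balanced' or 'none'")


class WindowPrediction(NamedTuple):
    child_id: str
    window_index: int
    p_insecure: float
    hard_label: BinaryLabel


@dataclass(frozen=True)
class ChildRating:
    """Majority-vote rating of one child."""

    child_id: str
    label: BinaryLabel
    vote_fraction: float
    n_windows: int


@dataclass
class Model:
    """A trained window classifier plus its feature-normalisation state."""

    spec: ModelSpec
    schema_hash: str
    mean: np.ndarray
    std: np.ndarray
    backend: object  # GRUClassifier | LogisticRegression
    feature_mask: np.ndarray | None = None  # optional channel subset


def _window_tensor(windows: Sequence[FeatureWindow]) -> np.ndarray:
    shapes = {w.frames.shape for w in windows}
    if len(shapes) > 1:
        raise SchemaError(f"inconsistent window shapes: {sorted(shapes)}")
    return np.stack([w.frames for w in windows])


def _summary_matrix(X: np.ndarray) -> np.ndarray:
    """Per-window summaries: mean/std of continuous channels + proportions."""
    cont = [FEATURE_COLUMNS.index(c) for c in CONTINUOUS_COLUMNS]
    flags = [
        FEATURE_COLUMNS.index(c)
        for c in ("dist_valid", "left_present", "right_present")
    ]
    mean = X[:, :, cont].mean(axis=1)
    std = X[:, :, cont].std(axis=1)
    props = X[:, :, flags].mean(axis=1)
    return np.concatenate([mean, std, props], axis=1)


def _labels_vector(windows: Sequence[FeatureWindow]) -> np.ndarray:
    y = np.empty(len(windows))
    for i, w in enumerate(windows):
        if w.label is None:
            raise ValueError(f"window {w.child_id}/{w.window_index} has no label")
        y[i] = 0.0 if w.label.secure else 1.0
    return y


def _sample_weights(y: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "none":
        return np.ones(len(y))
    n = len(y)
    w = np.ones(n)
    for cls in (0.0, 1.0):
        mask = y == cls
        w[mask] = n / (2.0 * mask.sum())
    return w


def train(
    windows: Sequence[FeatureWindow],
    spec: ModelSpec,
    feature_mask: Sequence[str] | None = None,
) -> Model:
    """Fit a window classifier on labelled windows.

    ``feature_mask`` optionally restricts the model to a named subset of
    feature columns (e.g. only the inter-hand distance family).
    """
    if not windows:
        raise DegenerateInputError("no training windows")
    y = _labels_vector(windows)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training set contains a single class")
    X = _window_tensor(windows)

    mask = None
    if feature_mask is not None:
        idx = [FEATURE_COLUMNS.index(c) for c in feature_mask]
        mask = np.zeros(len(FEATURE_COLUMNS), dtype=bool)
        mask[idx] = True
        X = X[:, :, mask]

    sw = _sample_weights(y, spec.class_weighting)

    if spec.backend == "recurrent-sequence":
        mean = X.mean(axis=(0, 1))
        std = np.maximum(X.std(axis=(0, 1)), 1e-8)
        Xn = (X - mean) / std
        net = GRUClassifier(
            n_features=Xn.shape[2],
            hidden_size=spec.hidden_size,
            epochs=spec.epochs,
            learning_rate=spec.learning_rate,
            seed=spec.seed,
        )
        net.fit(Xn, y, sample_weight=sw)
        backend = net
    else:
        S = _summary_matrix(X) if mask is None else _raw_summary(X)
        mean = S.mean(axis=0)
        std = np.maximum(S.std(axis=0), 1e-8)
        Sn = (S - mean) / std
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(Sn, y, sample_weight=sw)
        backend = clf

    return Model(
        spec=spec,
        schema_hash=feature_schema_hash(),
        mean=mean,
        std=std,
        backend=backend,
        feature_mask=mask,
    )


def _raw_summary(X: np.ndarray) -> np.ndarray:
    """Mean/std summaries over whatever channels remain after masking."""
    return np.concatenate([X.mean(axis=1), X.std(axis=1)], axis=1)


def predict_windows(
    model: Model, windows: Sequence[FeatureWindow]
) -> list[WindowPrediction]:
    """Classify each window independently; pure function of (model, windows)."""
    if not windows:
        return []
    for w in windows:
        if feature_schema_hash(w.columns) != model.schema_hash:
            raise SchemaError(
                f"window {w.child_id}/{w.window_index} feature schema does not "
                "match the model's"
            )
    X = _window_tensor(windows)
    if model.feature_mask is not None:
        X = X[:, :, model.feature_mask]
    if model.spec.backend == "recurrent-sequence":
        Xn = (X - model.mean) / model.std
        p = model.backend.predict_proba(Xn)
    else:
        S = _summary_matrix(X) if model.feature_mask is None else _raw_summary(X)
        if S.shape[1] != len(model.mean):
            raise SchemaError("summary dimensionality does not match the model")
        Sn = (S - model.mean) / model.std
        p = model.backend.predict_proba(Sn)[:, list(model.backend.classes_).index(1.0)]
    out = []
    for w, pi in zip(windows, p):
        hard = BinaryLabel.INSECURE if pi >= 0.5 else BinaryLabel.SECURE
        out.append(WindowPrediction(w.child_id, w.window_index, float(pi), hard))
    return out


def majority_vote(
    predictions: Sequence[WindowPrediction],
    cap: int | None = 500,
    tie_break: BinaryLabel = BinaryLabel.INSECURE,
) -> ChildRating:
    """Aggregate one child's window decisions into a rating.

    Uses the first ``min(n, cap)`` windows in temporal order; the child is
    assigned the modal window label, exact ties resolving to ``tie_break``
    (default insecure).  ``vote_fraction`` is the share of counted windows
    voting for the assigned label, hence always in [0.5, 1].
    """
    if not predictions:
        raise ValueError("no predictions to aggregate")
    ids = {p.child_id for p in predictions}
    if len(ids) > 1:
        raise ValueError(f"predictions mix children: {sorted(ids)}")
    ordered = sorted(predictions, key=lambda p: p.window_index)
    if cap is not None:
        ordered = ordered[:cap]
    n = len(ordered)
    n_insecure = sum(1 for p in ordered if p.hard_label is BinaryLabel.INSECURE)
    n_secure = n - n_insecure
    if n_insecure > n_secure:
        label = BinaryLabel.INSECURE
    elif n_secure > n_insecure:
        label = BinaryLabel.SECURE
    else:
        label = tie_break
    votes = n_insecure if label is BinaryLabel.INSECURE else n_secure
    return ChildRating(
        child_id=ordered[0].child_id,
        label=label,
        vote_fraction=votes / n,
        n_windows=n,
    )


# -- model persistence ------------------------------------------------------


def save_model(model: Model, path: str | Path) -> None:
    """Serialise a model (spec, scaler, weights, schema hash) to JSON."""
    d: dict = {
        "spec": asdict(model.spec),
        "schema_hash": model.schema_hash,
        "mean": np.asarray(model.mean).tolist(),
        "std": np.asarray(model.std).tolist(),
        "feature_mask": (
            None if model.feature_mask is None else model.feature_mask.tolist()
        ),
    }
    if model.spec.backend == "recurrent-sequence":
        d["backend"] = model.backend.to_dict()
    else:
        clf = model.backend
        d["backend"] = {
            "coef": clf.coef_.tolist(),
            "intercept": clf.intercept_.tolist(),
            "classes": clf.classes_.tolist(),
        }
    Path(path).write_text(json.dumps(d))


def load_model(path: str | Path) -> Model:
    d = json.loads(Path(path).read_text())
    spec = ModelSpec(**d["spec"])
    if spec.backend == "recurrent-sequence":
        backend: object = GRUClassifier.from_dict(d["backend"])
    else:
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.coef_ = np.asarray(d["backend"]["coef"])
        clf.intercept_ = np.asarray(d["backend"]["intercept"])
        clf.classes_ = np.asarray(d["backend"]["classes"])
        backend = clf
    mask = d["feature_mask"]
    return Model(
        spec=spec,
        schema_hash=d["schema_hash"],
        mean=np.asarray(d["mean"]),
        std=np.asarray(d["std"]),
        backend=backend,
        feature_mask=None if mask is None else np.asarray(mask, dtype=bool),
    )
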
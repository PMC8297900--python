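"""Inter-measure / inter-rater agreement on categorical attachment codings.

Two raters (or two instruments, e.g. SAM's automatic rater against the
manual MCAST coding) each assign one of k categories to every case.  The
k x k confusion matrix of their joint assignments supports three summary
statistics:

* percent agreement  ``100 * trace / N``,
* the discordance count ``N - trace``,
* Cohen's kappa ``(p_o - p_e) / (1 - p_e)`` with ``p_o = trace / N`` and
  ``p_e = sum_i row_i * col_i / N**2`` — agreement corrected for the
  agreement expected by chance from the marginals.

Four-way ABCD matrices can be collapsed to the two standard binary schemes
(secure/insecure, organised/disorganised) before computing the statistics.
Matrices are stored with a fixed category order; for ABCD it is (B, A, C, D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .labels import CATEGORY_ORDER, AttachmentLabel

__all__ = [
    "ConfusionMatrixK",
    "AgreementResult",
    "collapse",
    "percent_agreement",
    "cohen_kappa",
    "pair_to_confusion",
    "agreement_report",
    "COLLAPSE_SCHEMES",
]

#: scheme name -> (category name for the first merged block, membership test)
COLLAPSE_SCHEMES = {
    "secure-insecure": (
        ("secure", "insecure"),
        lambda code: AttachmentLabel.from_code(code).secure,
    ),
    "organised-disorganised": (
        ("organised", "disorganised"),
        lambda code: AttachmentLabel.from_code(code).organised,
    ),
}


@dataclass(frozen=True)
class ConfusionMatrixK:
    """k x k contingency table; rows = measure 1, columns = measure 2."""

    categories: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.categories)
        if counts.shape != (k, k):
            raise SchemaError(
                f"counts shape {counts.shape} does not match {k} categories"
            )
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return len(self.categories)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def agreeing(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.categories), columns=list(self.categories)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="")

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrixK":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise SchemaError("confusion CSV must have identical row/column labels")
        return cls(tuple(str(c) for c in df.columns), df.to_numpy())


@dataclass(frozen=True)
class AgreementResult:
    """Agreement summary for one confusion matrix."""

    n: int
    percent_agreement: float  # 0..100, full precision
    discordant: int
    kappa: float

    @property
    def percent_display(self) -> int:
        """Percent agreement at the conventional display rounding."""
        return int(round(self.percent_agreement))

    @property
    def kappa_display(self) -> float:
        """Kappa rounded to two decimals, as conventionally reported."""
        return round(self.kappa, 2)


def pair_to_confusion(
    pairs: Iterable[tuple[str, str]],
    categories: Sequence[str] = CATEGORY_ORDER,
) -> ConfusionMatrixK:
    """Tabulate (label1, label2) pairs into a confusion matrix.

    Raises ``ValueError`` on an empty pair list or a label outside
    ``categories``.
    """
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    n = 0
    for a, b in pairs:
        try:
            counts[index[str(a)], index[str(b)]] += 1
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in categories {categories}")
        n += 1
    if n == 0:
        raise ValueError("cannot tabulate an empty pair list")
    return ConfusionMatrixK(categories, counts)


def collapse(cm: ConfusionMatrixK, scheme: str) -> ConfusionMatrixK:
    """Collapse a 4x4 ABCD matrix to one of the two binary schemes.

    ``secure-insecure`` merges {A, C, D}; ``organised-disorganised`` merges
    {B, A, C}.  The total count is preserved.
    """
    if scheme not in COLLAPSE_SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(COLLAPSE_SCHEMES)}"
        )
    names, in_first = COLLAPSE_SCHEMES[scheme]
    if cm.k != 4:
        raise SchemaError(f"collapse expects a 4x4 ABCD matrix, got {cm.k}x{cm.k}")
    group = np.array([0 if in_first(c) else 1 for c in cm.categories])
    counts = np.zeros((2, 2), dtype=np.int64)
    for i in range(cm.k):
        for j in range(cm.k):
            counts[group[i], group[j]] += cm.counts[i, j]
    return ConfusionMatrixK(names, counts)


def percent_agreement(cm: ConfusionMatrixK) -> tuple[float, int]:
    """Return (percent agreement at full precision, discordant count)."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    agreeing = cm.agreeing
    return 100.0 * agreeing / cm.n, cm.n - agreeing


def cohen_kappa(cm: ConfusionMatrixK) -> float:
    """Cohen's kappa of a confusion matrix.

    Returns NaN (with a warning) when the chance agreement ``p_e`` is 1,
    i.e. both marginals are concentrated on a single identical category.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    p_o = np.trace(counts) / n
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    p_e = float(row @ col) / (n * n)
    if p_e >= 1.0 - 1e-15:
        warnings.warn("chance agreement is 1; kappa undefined", RuntimeWarning)
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def agreement_report(cm: ConfusionMatrixK) -> AgreementResult:
    """Bundle n, percent agreement, discordance and kappa for one matrix."""
    pct, discordant = percent_agreement(cm)
    return AgreementResult(
        n=cm.n, percent_agreement=pct, discordant=discordant, kappa=cohen_kappa(cm)
    )
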
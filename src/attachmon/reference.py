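"""Published reference figures from the SAM validation study.

These printed tables are inputs to the concordance and metric checks: the
4x4 SAM x MCAST inter-measure confusion matrix (61 children rated with both
instruments, rows = SAM manual coding, columns = MCAST coding, category
order B, A, C, D) and the reported performance of the automatic rater
against manual SAM coding on 105 children (secure vs insecure; the positive
class for precision/recall is insecure).
"""

from __future__ import annotations

import numpy as np

from .agreement import ConfusionMatrixK
from .labels import CATEGORY_ORDER

__all__ = [
    "sam_mcast_confusion",
    "AUTOMATIC_RATER_METRICS",
    "AUTOMATIC_RATER_CONFUSION",
    "CHILD_LEVEL_AGREEMENT_PERCENT",
]

_SAM_MCAST_COUNTS = np.array(
    [
        [39, 2, 1, 0],  # SAM B
        [0, 2, 1, 0],  # SAM A
        [2, 0, 8, 0],  # SAM C
        [2, 0, 0, 4],  # SAM D
    ],
    dtype=np.int64,
)


def sam_mcast_confusion() -> ConfusionMatrixK:
    """The published SAM x MCAST four-way confusion matrix (N = 61)."""
    return ConfusionMatrixK(CATEGORY_ORDER, _SAM_MCAST_COUNTS.copy())


#: Reported automatic-vs-manual performance (percent): accuracy, precision,
#: recall, F1, with insecure as positive class.
AUTOMATIC_RATER_METRICS = {"alpha": 80.2, "pi": 67.4, "rho": 91.2, "f1": 77.5}

#: Child-level confusion consistent with the reported precision/recall and
#: the 87/105 child-level agreement (positive class = insecure).
AUTOMATIC_RATER_CONFUSION = {"tp": 31, "fp": 15, "fn": 3, "tn": 56}

#: Reported child-level secure/insecure agreement between automatic and
#: manual rating: 87 of 105 children.
CHILD_LEVEL_AGREEMENT_PERCENT = 82.8
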
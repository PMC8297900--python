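"""Four-way attachment codes and their canonical binary collapses.

The ABCD scheme codes a child's attachment pattern from observed doll-play
behaviour: B (secure), A (insecure-avoidant), C (insecure-ambivalent) and
D (insecure-disorganised).  Two binary collapses are standard: secure vs
insecure (B vs A/C/D) and organised vs disorganised (B/A/C vs D).
"""

from __future__ import annotations

import enum

__all__ = ["AttachmentLabel", "CATEGORY_ORDER", "BinaryLabel"]

#: Fixed category order used for all 4x4 confusion matrices.
CATEGORY_ORDER: tuple[str, ...] = ("B", "A", "C", "D")


class AttachmentLabel(enum.Enum):
    """One four-way attachment code."""

    B = "B"
    A = "A"
    C = "C"
    D = "D"

    @classmethod
    def from_code(cls, code: str) -> "AttachmentLabel":
        code = str(code).strip().upper()
        try:
            return cls(code)
        except ValueError:
            raise ValueError(
                f"unknown attachment code {code!r}; expected one of B, A, C, D"
            ) from None

    @property
    def secure(self) -> bool:
        """True iff the code is B."""
        return self is AttachmentLabel.B

    @property
    def organised(self) -> bool:
        """True iff the code is not D."""
        return self is not AttachmentLabel.D

    def binary(self) -> "BinaryLabel":
        """Secure/insecure projection used by the automatic rater."""
        return BinaryLabel.SECURE if self.secure else BinaryLabel.INSECURE

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class BinaryLabel(enum.Enum):
    """Secure/insecure binary rating produced by the classifier."""

    SECURE = "secure"
    INSECURE = "insecure"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value
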
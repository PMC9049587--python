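"""The nine heart-rhythm classes and their frozen ordering.

The class vocabulary covers normal sinus rhythm plus eight common
arrhythmias/morphology abnormalities seen on a standard 12-lead ECG.
The integer index of each class is frozen: downstream feature assembly
drops the *last* class probability of each per-lead softmax vector
("first eight probabilities" rule), so the order below is load-bearing
and must never be reordered.
"""

from __future__ import annotations

import enum


class ClassLabel(enum.Enum):
    """Rhythm class with a frozen ``code <-> index`` bijection.

    Members are ordered: N, AF, I-AVB, LBBB, RBBB, PAC, PVC, STD, STE
    with indices 0..8 in exactly that order.
    """

    N = 0        # normal sinus rhythm
    AF = 1       # atrial fibrillation
    I_AVB = 2    # first-degree atrioventricular block
    LBBB = 3     # left bundle branch block
    RBBB = 4     # right bundle branch block
    PAC = 5      # premature atrial contraction
    PVC = 6      # premature ventricular contraction
    STD = 7      # ST-segment depression
    STE = 8      # ST-segment elevation

    @property
    def code(self) -> str:
        """Display code, e.g. ``'I-AVB'`` for ``ClassLabel.I_AVB``."""
        return self.name.replace("_", "-")

    @property
    def index(self) -> int:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "ClassLabel":
        """Parse a display code (``'I-AVB'``) or member name (``'I_AVB'``)."""
        key = code.strip().replace("-", "_")
        try:
            return cls[key]
        except KeyError:
            raise ValueError(
                f"unknown class label {code!r}; expected one of "
                f"{[m.code for m in cls]}"
            ) from None

    @classmethod
    def from_index(cls, index: int) -> "ClassLabel":
        try:
            return cls(index)
        except ValueError:
            raise ValueError(f"class index must be 0..8, got {index}") from None


#: All nine classes in frozen index order.
ALL_CLASSES: tuple[ClassLabel, ...] = tuple(ClassLabel)

#: Display codes in frozen index order.
CLASS_CODES: tuple[str, ...] = tuple(c.code for c in ALL_CLASSES)

N_CLASSES: int = len(ALL_CLASSES)
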
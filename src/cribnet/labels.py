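"""Tissue label vocabulary and per-class loss weights.

The detection task distinguishes seven classes: a catch-all ``non-labelled``
class (background, stroma, benign tissue and rare patterns), Gleason grade 3,
and the five Gleason grade 4 growth patterns.  The cribriform pattern is the
clinically relevant target and carries a higher loss weight than the auxiliary
classes, which are present only to sharpen the decision boundary during
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_LABELS = (
    "non-labelled",
    "G3",
    "G4 fused",
    "G4 ill-defined",
    "G4 complex fused",
    "G4 glomeruloid",
    "G4 cribriform",
)

NON_LABELLED = "non-labelled"
CRIBRIFORM = "G4 cribriform"


@dataclass(frozen=True)
class LabelSet:
    """Ordered 7-class vocabulary with per-class loss weights ``w_l``.

    Weights must sum to 1; the default puts 0.4 on the cribriform class and
    0.1 on each of the six other classes.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    weights: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            w = tuple(0.4 if l == CRIBRIFORM else 0.1 for l in self.labels)
            object.__setattr__(self, "weights", w)
        if len(self.labels) != 7:
            raise ValueError(f"expected exactly 7 labels, got {len(self.labels)}")
        if len(self.weights) != len(self.labels):
            raise ValueError("weights and labels must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1, got {sum(self.weights)!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        """Case-insensitive lookup of a label's position."""
        needle = label.strip().lower()
        for i, name in enumerate(self.labels):
            if name.lower() == needle:
                return i
        raise KeyError(f"unknown label {label!r}; known labels: {list(self.labels)}")

    def canonical(self, label: str) -> str:
        return self.labels[self.index(label)]

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)

    @property
    def non_labelled_index(self) -> int:
        return self.index(NON_LABELLED)

    @property
    def cribriform_index(self) -> int:
        return self.index(CRIBRIFORM)
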
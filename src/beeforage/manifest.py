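"""Training-dataset manifest bookkeeping.

A manifest records, per split (test / train / validation), how many
images carry object labels and how many were added as unlabelled
false-positive examples; totals are derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from beeforage.errors import ParameterError

__all__ = ["SplitCounts", "DatasetManifest"]


@dataclass(frozen=True)
class SplitCounts:
    """Image counts for one split."""

    labelled: int
    false_positive: int

    def __post_init__(self) -> None:
        if self.labelled < 0 or self.false_positive < 0:
            raise ParameterError("image counts must be non-negative")

    @property
    def total(self) -> int:
        return self.labelled + self.false_positive


@dataclass(frozen=True)
class DatasetManifest:
    """Per-split image counts for one species' detection dataset."""

    species: str
    test: SplitCounts
    train: SplitCounts
    validation: SplitCounts

    @property
    def splits(self) -> Dict[str, SplitCounts]:
        return {"test": self.test, "train": self.train, "validation": self.validation}

    def total_labelled(self) -> int:
        return sum(s.labelled for s in self.splits.values())

    def total_false_positive(self) -> int:
        return sum(s.false_positive for s in self.splits.values())

    def total(self) -> int:
        """All images in the dataset: labelled plus false-positive, all splits."""
        return sum(s.total for s in self.splits.values())
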
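"""Enumeration of the feature-selection x classifier settings grid.

Two-level selection: one of 7 filter methods screens features first, one of
8 embedded methods picks the final subset, and one of 13 classifiers is
fitted — 7 x 8 x 13 = 728 settings in the full grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Sequence

FILTER_METHODS = ("CHSQ", "TSQ", "KWH", "VAR", "RELF", "MI", "mRMRe")
EMBEDDED_METHODS = ("L1-LR", "EN", "LASSO", "L1-SVM", "RF", "ETE", "GBDT", "XGB")
CLASSIFIERS = (
    "GNB", "MNB", "BNB", "KNN", "RF", "BAG", "DT",
    "GBDT", "Adaboost", "XGB", "LDA", "LR", "SVM",
)


@dataclass(frozen=True)
class PipelineSetting:
    filter_method: str
    embedded_method: str
    classifier: str
    first_level_keep: int = 100
    max_selected: int = 10

    @property
    def name(self) -> str:
        return f"{self.filter_method}+{self.embedded_method}+{self.classifier}"


def enumerate_grid(
    filter_methods: Sequence[str] = FILTER_METHODS,
    embedded_methods: Sequence[str] = EMBEDDED_METHODS,
    classifiers: Sequence[str] = CLASSIFIERS,
    first_level_keep: int = 100,
    max_selected: int = 10,
) -> List[PipelineSetting]:
    """Full Cartesian product in stable (filter, embedded, classifier) order."""
    if not (filter_methods and embedded_methods and classifiers):
        raise ValueError("method enums must be non-empty")
    return [
        PipelineSetting(f, e, c, first_level_keep, max_selected)
        for f, e, c in product(filter_methods, embedded_methods, classifiers)
    ]
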
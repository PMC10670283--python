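"""Feature schema: the ordered column list of the radiomics feature table.

Per sequence: 14 shape features computed from the mask, plus, on each of
the 17 filter images, 18 first-order and 75 texture features (24 GLCM +
16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM), i.e. 14 + 17 x 93 = 1595
features; a two-sequence case yields 3190.  Column names are
``sequence__filter__class__feature``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from radaug.features.filters import filter_names
from radaug.features.firstorder import FIRSTORDER_NAMES
from radaug.features.shape import SHAPE_NAMES
from radaug.features.texture import TEXTURE_CLASS_NAMES

TEXTURE_CLASSES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")
ALL_CLASSES = ("shape", "firstorder") + TEXTURE_CLASSES


@dataclass(frozen=True)
class SchemaEntry:
    sequence: str
    filter_name: str
    feature_class: str
    feature_name: str

    @property
    def column(self) -> str:
        return f"{self.sequence}__{self.filter_name}__{self.feature_class}__{self.feature_name}"


@dataclass(frozen=True)
class ExtractionProfile:
    """Which filters and feature classes to extract.

    The default is the full 17-filter, 7-class schema.  Reduced profiles
    (e.g. original filter with shape + first-order + GLCM only) are used
    for large repeated-CV experiments where the full schema would dominate
    runtime.
    """

    filters: Tuple[str, ...] = tuple(filter_names())
    classes: Tuple[str, ...] = ALL_CLASSES

    @staticmethod
    def light() -> "ExtractionProfile":
        return ExtractionProfile(filters=("original",), classes=("shape", "firstorder", "glcm"))

    @staticmethod
    def original_filter() -> "ExtractionProfile":
        """All seven feature classes on the unfiltered image only."""
        return ExtractionProfile(filters=("original",), classes=ALL_CLASSES)


def class_feature_names(feature_class: str) -> Sequence[str]:
    if feature_class == "shape":
        return SHAPE_NAMES
    if feature_class == "firstorder":
        return FIRSTORDER_NAMES
    return TEXTURE_CLASS_NAMES[feature_class]


def build_schema(sequences: Sequence[str], profile: ExtractionProfile = ExtractionProfile()) -> List[SchemaEntry]:
    """Ordered schema: per sequence, shape first, then per-filter classes."""
    entries: List[SchemaEntry] = []
    for seq in sequences:
        if "shape" in profile.classes:
            for name in SHAPE_NAMES:
                entries.append(SchemaEntry(seq, "original", "shape", name))
        for filt in profile.filters:
            for cls in profile.classes:
                if cls == "shape":
                    continue
                for name in class_feature_names(cls):
                    entries.append(SchemaEntry(seq, filt, cls, name))
    return entries


def schema_columns(schema: Sequence[SchemaEntry]) -> List[str]:
    return [e.column for e in schema]


def save_schema(schema: Sequence[SchemaEntry], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"sequence": e.sequence, "filter": e.filter_name, "class": e.feature_class, "feature": e.feature_name}
                for e in schema
            ],
            fh,
            indent=1,
        )


def load_schema(path: str) -> List[SchemaEntry]:
    with open(path) as fh:
        raw = json.load(fh)
    return [SchemaEntry(r["sequence"], r["filter"], r["class"], r["feature"]) for r in raw]
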
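"""Feature extraction driver: case -> feature row, cohort -> feature table."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from radaug.types import AugmentedCase, VolumeCase
from radaug.features import matrices as mx
from radaug.features import texture as tx
from radaug.features.filters import build_filter_bank
from radaug.features.firstorder import firstorder_features
from radaug.features.preprocess import PreprocessConfig, preprocess
from radaug.features.schema import ExtractionProfile, SchemaEntry, build_schema
from radaug.features.shape import shape_features


def _texture_block(image, mask, bin_width, classes) -> Dict[str, Dict[str, float]]:
    disc, ng = mx.discretize(image, mask, bin_width)
    n_vox = int((disc > 0).sum())
    out = {}
    if "glcm" in classes:
        out["glcm"] = tx.glcm_features(mx.glcm_matrices(disc, ng))
    if "glrlm" in classes:
        out["glrlm"] = tx.glrlm_features(mx.glrlm_matrices(disc, ng), n_vox)
    if "glszm" in classes:
        out["glszm"] = tx.glszm_features(mx.glszm_matrix(disc, ng), n_vox)
    if "ngtdm" in classes:
        out["ngtdm"] = tx.ngtdm_features(*mx.ngtdm_components(disc, ng))
    if "gldm" in classes:
        out["gldm"] = tx.gldm_features(mx.gldm_matrix(disc, ng), n_vox)
    return out


def extract_features(
    case: VolumeCase,
    config: PreprocessConfig = PreprocessConfig(),
    profile: ExtractionProfile = ExtractionProfile(),
    preprocessed: bool = False,
) -> Dict[str, float]:
    """Extract one feature row (column name -> value) for a case.

    Shape features are computed once per sequence from the resampled mask;
    first-order and texture features are computed on every filter image.
    Any non-finite value is a defect and raises immediately.
    """
    pcase = case if preprocessed else preprocess(case, config)
    mask = pcase.mask.astype(bool)
    voxel_volume = float(np.prod(pcase.spacing_mm))
    row: Dict[str, float] = {}
    shape_vals = shape_features(mask, pcase.spacing_mm) if "shape" in profile.classes else None
    for seq, image in pcase.images.items():
        if shape_vals is not None:
            for name, val in shape_vals.items():
                row[f"{seq}__original__shape__{name}"] = val
        bank = build_filter_bank(image, pcase.spacing_mm, only=profile.filters)
        for filt in profile.filters:
            fimg = bank[filt]
            if "firstorder" in profile.classes:
                fo = firstorder_features(fimg[mask], voxel_volume, config.bin_width)
                for name, val in fo.items():
                    row[f"{seq}__{filt}__firstorder__{name}"] = val
            tex_classes = [c for c in profile.classes if c in tx.TEXTURE_CLASS_NAMES]
            if tex_classes:
                blocks = _texture_block(fimg, mask, config.bin_width, tex_classes)
                for cls, feats in blocks.items():
                    for name, val in feats.items():
                        row[f"{seq}__{filt}__{cls}__{name}"] = val
    bad = [k for k, v in row.items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(f"non-finite feature values: {bad[:5]} ...")
    return row


class FeatureTable:
    """Cases x features matrix with labels and parent-case grouping."""

    def __init__(self, features: pd.DataFrame, labels: pd.Series, parent_id: pd.Series):
        if not features.index.equals(labels.index) or not features.index.equals(parent_id.index):
            raise ValueError("features, labels and parent_id must share an index")
        self.features = features
        self.labels = labels.astype(int)
        self.parent_id = parent_id

    def __len__(self) -> int:
        return len(self.features)

    @property
    def columns(self) -> List[str]:
        return list(self.features.columns)

    def subset_rows(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.features.loc[ids], self.labels.loc[ids], self.parent_id.loc[ids])

    def subset_columns(self, cols: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.features[list(cols)], self.labels, self.parent_id)

    def to_csv(self, path: str) -> None:
        out = self.features.copy()
        out.insert(0, "label", self.labels)
        out.insert(1, "parent_id", self.parent_id)
        # %.17g is round-trip exact for float64
        out.to_csv(path, index_label="case_id", float_format="%.17g")

    @staticmethod
    def from_csv(path: str) -> "FeatureTable":
        df = pd.read_csv(path, index_col="case_id", float_precision="round_trip")
        labels = df.pop("label")
        parent = df.pop("parent_id")
        return FeatureTable(df, labels, parent)


def extract_table(
    cases: Sequence[VolumeCase],
    config: PreprocessConfig = PreprocessConfig(),
    profile: ExtractionProfile = ExtractionProfile(),
) -> FeatureTable:
    rows, labels, parents, ids = [], [], [], []
    for case in cases:
        rows.append(extract_features(case, config, profile))
        labels.append(case.label)
        parents.append(case.parent_id if isinstance(case, AugmentedCase) else case.case_id)
        ids.append(case.case_id)
    df = pd.DataFrame(rows, index=ids)
    return FeatureTable(df, pd.Series(labels, index=ids), pd.Series(parents, index=ids))
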
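"""Serializable run configuration: one YAML file reproduces a whole run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Tuple

import yaml

from radaug.augment import AugmentationRecipe
from radaug.experiment import ExperimentConfig
from radaug.features.preprocess import PreprocessConfig
from radaug.features.schema import ExtractionProfile
from radaug.grid import PipelineSetting
from radaug.types import PhantomConfig


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    recipe: AugmentationRecipe = field(default_factory=AugmentationRecipe)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    profile: ExtractionProfile = field(default_factory=ExtractionProfile.light)
    setting: PipelineSetting = field(default_factory=lambda: PipelineSetting("CHSQ", "LASSO", "LR"))
    modes: Tuple[str, ...] = ("None", "FA", "IA", "IAFA")
    folds: Tuple[int, ...] = (3,)
    repetitions: int = 10
    smote_k: int = 5
    icc_threshold: float = 0.9
    master_seed: int = 0
    out_dir: str = "radaug_out"

    def experiment_config(self, k: int) -> ExperimentConfig:
        return ExperimentConfig(
            setting=self.setting,
            modes=tuple(self.modes),
            k=k,
            repetitions=self.repetitions,
            recipe=self.recipe,
            preprocess=self.preprocess,
            profile=self.profile,
            smote_k=self.smote_k,
            icc_threshold=self.icc_threshold,
            seed=self.master_seed,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def _tupled(d):
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        return RunConfig(
            phantom=PhantomConfig(**_tupled(raw["phantom"])),
            recipe=AugmentationRecipe(**raw["recipe"]),
            preprocess=PreprocessConfig(**_tupled(raw["preprocess"])),
            profile=ExtractionProfile(**_tupled(raw["profile"])),
            setting=PipelineSetting(**raw["setting"]),
            modes=tuple(raw["modes"]),
            folds=tuple(raw["folds"]),
            repetitions=raw["repetitions"],
            smote_k=raw["smote_k"],
            icc_threshold=raw["icc_threshold"],
            master_seed=raw["master_seed"],
            out_dir=raw["out_dir"],
        )

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
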
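"""Core in-memory containers: phantom configuration and image cases."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Dict, Mapping, Tuple

import numpy as np

Triple = Tuple[float, float, float]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic two-sequence phantom cohort.

    The cohort emulates an imbalanced binary tumor-grading problem: a
    majority (low-grade) and a minority (high-grade) class whose tumors
    differ in intensity heterogeneity (texture-noise amplitude inside the
    mask) and margin irregularity (radial perturbation of an ellipsoidal
    boundary).  ``heterogeneity_minority > heterogeneity_majority`` is the
    separating signal; setting them equal (and the irregularity to zero)
    yields a null cohort with no class signal.
    """

    n_majority: int = 129
    n_minority: int = 31
    volume_shape: Tuple[int, int, int] = (32, 32, 32)
    spacing_mm: Triple = (1.0, 1.0, 1.0)
    tumor_radius_range_mm: Tuple[float, float] = (5.0, 9.0)
    heterogeneity_majority: float = 0.10
    heterogeneity_minority: float = 0.22
    margin_irregularity_minority: float = 0.25
    base_intensity_per_sequence: Tuple[float, float] = (300.0, 450.0)
    sequence_names: Tuple[str, str] = ("T2W", "T1C")
    background_fraction: float = 0.55
    noise_fraction: float = 0.02
    sequence_correlation: float = 0.7
    heterogeneity_jitter_sigma: float = 0.15
    # per-case acquisition nuisance (label-independent): smooth multiplicative
    # bias field, gamma-like contrast shift, and variable noise level —
    # emulates scanner/protocol variation across a single-center cohort
    acquisition_bias: float = 0.15
    acquisition_gamma_log: float = 0.2
    acquisition_psf_sigma_mm: Tuple[float, float] = (0.2, 0.8)
    master_seed: int = 0

    def validate(self) -> None:
        if not (self.n_majority >= self.n_minority >= 2):
            raise ValueError("need n_majority >= n_minority >= 2")
        if not self.heterogeneity_minority > self.heterogeneity_majority >= 0:
            raise ValueError(
                "heterogeneity_minority must exceed heterogeneity_majority "
                "(use a null config explicitly via allow_null=True paths)"
            )
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        lo, hi = self.tumor_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range_mm must be a positive interval")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        # largest perturbed radius plus center jitter must fit in the volume
        for dim, sp in zip(self.volume_shape, self.spacing_mm):
            half_extent = dim * sp / 2.0
            needed = hi * (1.0 + max(self.margin_irregularity_minority, 0.0)) + 0.1 * dim * sp
            if needed >= half_extent:
                raise ValueError(
                    f"volume too small to contain tumor_radius_range {self.tumor_radius_range_mm} "
                    f"(dim {dim} at spacing {sp})"
                )

    def validate_null_allowed(self) -> None:
        """Validation variant that permits zero class signal (null cohorts)."""
        if not (self.n_majority >= self.n_minority >= 2):
            raise ValueError("need n_majority >= n_minority >= 2")
        if self.heterogeneity_minority < self.heterogeneity_majority:
            raise ValueError("heterogeneity_minority must be >= heterogeneity_majority")
        self._validate_geometry()


@dataclass
class VolumeCase:
    """One subject: co-registered 3D volumes per sequence, mask, label."""

    case_id: str
    images: Dict[str, np.ndarray]
    mask: np.ndarray
    spacing_mm: Triple
    label: int

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("all images and the mask must share one grid shape")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground voxel")

    @property
    def sequence_names(self) -> Tuple[str, ...]:
        return tuple(self.images)

    def copy(self) -> "VolumeCase":
        return VolumeCase(
            case_id=self.case_id,
            images={k: v.copy() for k, v in self.images.items()},
            mask=self.mask.copy(),
            spacing_mm=self.spacing_mm,
            label=self.label,
        )


@dataclass
class AugmentedCase(VolumeCase):
    """A derived case with augmentation provenance."""

    parent_id: str = ""
    op_kind: str = ""
    op_params: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0


MORPHOLOGICAL_OPS = ("affine_rotation", "elastic_deformation")
INTENSITY_OPS = ("motion", "bias_field", "noise", "blur", "gamma")
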
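"""Image-level augmentation (IA): MRI-specific perturbations of a case.

Two op families:

* morphological — ``affine_rotation``, ``elastic_deformation``: one shared
  geometric transform is applied to every sequence (linear interpolation)
  and to the mask (nearest-neighbor, preserving binariness), since the
  sequences are co-registered and must stay so.  These ops change shape
  features.
* intensity — ``motion``, ``bias_field``, ``noise``, ``blur``, ``gamma``:
  only voxel intensities change; the mask is bit-identical to the parent's,
  so shape features are exactly preserved.

The default recipe is 9 augmented copies per case: 3 affine rotations,
1 elastic deformation, 1 motion, 1 bias field, 1 noise, 1 blur, 1 gamma.
Parameter ranges are configurable; defaults are small, realistic MR-style
perturbations (rotations within ±10°, elastic displacement ≤ 7.5 mm on a
7³ control grid, order-3 bias polynomial with coefficients within ±0.5,
noise sigma up to 0.25 of the image SD, blur sigma up to 2 mm, gamma
log-uniform in ±0.3, motion ghosting from 2 small rigid transforms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Tuple

import numpy as np
from scipy import ndimage

from radaug.types import INTENSITY_OPS, MORPHOLOGICAL_OPS, AugmentedCase, VolumeCase


@dataclass(frozen=True)
class AugmentationRecipe:
    n_affine: int = 3
    n_elastic: int = 1
    n_motion: int = 1
    n_bias: int = 1
    n_noise: int = 1
    n_blur: int = 1
    n_gamma: int = 1
    rotation_deg: float = 10.0
    elastic_grid: int = 7
    elastic_max_mm: float = 7.5
    bias_order: int = 3
    bias_coeff: float = 0.5
    noise_sd_frac: float = 0.25
    blur_sigma_mm: float = 2.0
    gamma_log_range: float = 0.3
    motion_transforms: int = 2
    motion_deg: float = 10.0
    motion_mm: float = 10.0
    motion_max_ghost_weight: float = 0.15

    @staticmethod
    def small_volume() -> "AugmentationRecipe":
        """Magnitudes scaled for small (~16 mm) phantom volumes.

        The default ranges suit clinical-scale fields of view; on a 16 mm
        grid a 7.5 mm elastic displacement or 10 mm ghost shift would
        deform or ghost the whole tumor, so the spatial magnitudes are
        scaled down and the intensity perturbations kept at realistic MR
        levels (bias within roughly +/-20%, blur below the texture
        correlation length).
        """
        return AugmentationRecipe(
            elastic_max_mm=1.0,
            motion_deg=5.0,
            motion_mm=2.0,
            motion_max_ghost_weight=0.08,
            bias_coeff=0.05,
            noise_sd_frac=0.05,
            blur_sigma_mm=0.4,
            gamma_log_range=0.1,
        )

    @property
    def op_counts(self) -> Dict[str, int]:
        return {
            "affine_rotation": self.n_affine,
            "elastic_deformation": self.n_elastic,
            "motion": self.n_motion,
            "bias_field": self.n_bias,
            "noise": self.n_noise,
            "blur": self.n_blur,
            "gamma": self.n_gamma,
        }

    @property
    def total(self) -> int:
        return sum(self.op_counts.values())


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def _apply_rigid(volume: np.ndarray, matrix: np.ndarray, shift_vox: np.ndarray, order: int) -> np.ndarray:
    """Resample ``volume`` under x_out = R (x_in - c) + c + t, about the grid center."""
    center = (np.asarray(volume.shape, dtype=float) - 1.0) / 2.0
    # ndimage.affine_transform maps output coords to input coords: x_in = M x_out + offset
    inv = np.linalg.inv(matrix)
    offset = center - inv @ (center + shift_vox)
    return ndimage.affine_transform(volume, inv, offset=offset, order=order, mode="constant", cval=float(volume.min()) if order else 0.0, prefilter=order > 1)


def _elastic_displacement(rng: np.random.Generator, shape, grid: int, max_disp_vox: np.ndarray):
    coarse = rng.uniform(-1.0, 1.0, size=(3, grid, grid, grid))
    fields = []
    for axis in range(3):
        zoom = [s / grid for s in shape]
        fine = ndimage.zoom(coarse[axis], zoom, order=3, mode="nearest")
        fields.append(fine * max_disp_vox[axis])
    return fields


def apply_morphological(case: VolumeCase, kind: str, params: Dict[str, Any], seed: int) -> AugmentedCase:
    """Apply one shared geometric transform to all sequences and the mask.

    A draw that would push more than half of the mask outside the field of
    view is rejected and redrawn with the next seed.
    """
    if kind not in MORPHOLOGICAL_OPS:
        raise ValueError(f"unknown morphological op {kind!r}")
    spacing = np.asarray(case.spacing_mm, dtype=float)
    for attempt in range(16):
        rng = np.random.default_rng(seed + attempt)
        if kind == "affine_rotation":
            angles = params.get("angles_deg")
            if angles is None:
                angles = rng.uniform(-params.get("rotation_deg", 10.0), params.get("rotation_deg", 10.0), size=3)
            angles = np.asarray(angles, dtype=float)
            matrix = _rotation_matrix(angles)
            new_mask = _apply_rigid(case.mask.astype(np.uint8), matrix, np.zeros(3), order=0)
            drawn = {"angles_deg": angles.tolist()}
            transform_images = lambda im: _apply_rigid(im, matrix, np.zeros(3), order=1)  # noqa: E731
        else:
            max_mm = params.get("max_displacement_mm", 7.5)
            grid = int(params.get("control_grid", 7))
            max_vox = max_mm / spacing
            fields = _elastic_displacement(rng, case.mask.shape, grid, max_vox)
            coords = np.meshgrid(*[np.arange(s, dtype=float) for s in case.mask.shape], indexing="ij")
            sample = [c + f for c, f in zip(coords, fields)]
            new_mask = ndimage.map_coordinates(case.mask.astype(np.uint8), sample, order=0, mode="nearest")
            drawn = {"max_displacement_mm": max_mm, "control_grid": grid}
            transform_images = lambda im: ndimage.map_coordinates(im, sample, order=1, mode="nearest")  # noqa: E731
        if new_mask.sum() >= 0.5 * case.mask.sum() and new_mask.any():
            images = {name: transform_images(im) for name, im in case.images.items()}
            return AugmentedCase(
                case_id=f"{case.case_id}__{kind}_s{seed}",
                images=images,
                mask=new_mask.astype(np.uint8),
                spacing_mm=case.spacing_mm,
                label=case.label,
                parent_id=case.case_id,
                op_kind=kind,
                op_params=drawn,
                seed=seed,
            )
    raise RuntimeError(f"{kind}: could not draw a transform keeping >=50% of the mask in view")


def _bias_polynomial(rng: np.random.Generator, shape, order: int, coeff: float) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    poly = np.zeros(shape, dtype=float)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                c = rng.uniform(-coeff, coeff)
                poly += c * gx**i * gy**j * gz**k
    return poly


def evaluate_bias_field(coeffs: Dict[Tuple[int, int, int], float], shape) -> np.ndarray:
    """exp(polynomial) on the [-1,1]³ normalized grid, for explicit coefficients."""
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    poly = np.zeros(shape, dtype=float)
    for (i, j, k), c in coeffs.items():
        poly += c * gx**i * gy**j * gz**k
    return np.exp(poly)


def apply_intensity(case: VolumeCase, kind: str, params: Dict[str, Any], seed: int) -> AugmentedCase:
    """Apply an intensity-only op; the mask is bit-identical to the parent's."""
    if kind not in INTENSITY_OPS:
        raise ValueError(f"unknown intensity op {kind!r}")
    for im in case.images.values():
        if not np.all(np.isfinite(im)):
            raise ValueError("non-finite image values")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(case.spacing_mm, dtype=float)
    images: Dict[str, np.ndarray] = {}
    drawn: Dict[str, Any] = {}

    if kind == "bias_field":
        coeffs = params.get("coeffs")
        if coeffs is not None:
            field_img = evaluate_bias_field(coeffs, case.mask.shape)
            drawn["coeffs"] = {str(k): v for k, v in coeffs.items()}
        else:
            poly = _bias_polynomial(rng, case.mask.shape, int(params.get("order", 3)), params.get("coeff", 0.5))
            field_img = np.exp(poly)
            drawn["order"] = int(params.get("order", 3))
        images = {n: im * field_img for n, im in case.images.items()}
    elif kind == "noise":
        for n, im in case.images.items():
            sd = params.get("sigma")
            if sd is None:
                sd = rng.uniform(0.0, params.get("sd_frac", 0.25)) * im.std()
            images[n] = im + rng.normal(0.0, sd, size=im.shape) if sd > 0 else im.copy()
            drawn.setdefault("sigma", []).append(float(sd))
    elif kind == "blur":
        sigma_mm = params.get("sigma_mm")
        if sigma_mm is None:
            sigma_mm = rng.uniform(0.0, params.get("max_sigma_mm", 2.0))
        sig_vox = sigma_mm / spacing
        images = {
            n: ndimage.gaussian_filter(im, sig_vox) if sigma_mm > 0 else im.copy()
            for n, im in case.images.items()
        }
        drawn["sigma_mm"] = float(sigma_mm)
    elif kind == "gamma":
        gamma = params.get("gamma")
        if gamma is None:
            gamma = float(np.exp(rng.uniform(-params.get("log_range", 0.3), params.get("log_range", 0.3))))
        for n, im in case.images.items():
            lo, hi = im.min(), im.max()
            if hi > lo:
                norm = (im - lo) / (hi - lo)
                images[n] = norm**gamma * (hi - lo) + lo
            else:
                images[n] = im.copy()
        drawn["gamma"] = float(gamma)
    else:  # motion: faint ghost echoes — weighted mix with small rigid-transformed copies
        n_t = int(params.get("transforms", 2))
        deg = params.get("deg", 10.0)
        mm = params.get("mm", 10.0)
        ghost_total = rng.uniform(0.0, params.get("max_ghost_weight", 0.15))
        split = rng.dirichlet(np.ones(n_t)) if n_t > 1 else np.array([1.0])
        weights = np.concatenate([[1.0 - ghost_total], ghost_total * split])
        transforms = []
        for _ in range(n_t):
            ang = rng.uniform(-deg, deg, size=3)
            shift_vox = rng.uniform(-mm, mm, size=3) / spacing
            transforms.append((ang, shift_vox))
        for n, im in case.images.items():
            out = weights[0] * im
            for w, (ang, shift_vox) in zip(weights[1:], transforms):
                out = out + w * _apply_rigid(im, _rotation_matrix(ang), shift_vox, order=1)
            images[n] = out
        drawn["transforms"] = n_t
        drawn["weights"] = weights.tolist()

    return AugmentedCase(
        case_id=f"{case.case_id}__{kind}_s{seed}",
        images=images,
        mask=case.mask.copy(),
        spacing_mm=case.spacing_mm,
        label=case.label,
        parent_id=case.case_id,
        op_kind=kind,
        op_params=drawn,
        seed=seed,
    )


def run_ia_recipe(case: VolumeCase, recipe: AugmentationRecipe, seed: int) -> List[AugmentedCase]:
    """Produce the recipe's augmented copies (default 9); the original is not included."""
    out: List[AugmentedCase] = []
    counter = 0
    ss = np.random.SeedSequence(seed)
    op_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(recipe.total or 1)]
    for kind, count in recipe.op_counts.items():
        for _ in range(count):
            op_seed = op_seeds[counter % len(op_seeds)] + counter
            if kind in MORPHOLOGICAL_OPS:
                params = (
                    {"rotation_deg": recipe.rotation_deg}
                    if kind == "affine_rotation"
                    else {"max_displacement_mm": recipe.elastic_max_mm, "control_grid": recipe.elastic_grid}
                )
                out.append(apply_morphological(case, kind, params, op_seed))
            else:
                params = {
                    "motion": {
                        "transforms": recipe.motion_transforms,
                        "deg": recipe.motion_deg,
                        "mm": recipe.motion_mm,
                        "max_ghost_weight": recipe.motion_max_ghost_weight,
                    },
                    "bias_field": {"order": recipe.bias_order, "coeff": recipe.bias_coeff},
                    "noise": {"sd_frac": recipe.noise_sd_frac},
                    "blur": {"max_sigma_mm": recipe.blur_sigma_mm},
                    "gamma": {"log_range": recipe.gamma_log_range},
                }[kind]
                out.append(apply_intensity(case, kind, params, op_seed))
            counter += 1
    return out
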
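"""H&E color normalization and training-time augmentation.

Scanners and staining protocols shift the color distribution of slides enough
to hurt a model trained on other sites.  Two standard remedies are provided:

* **Stain-deconvolution normalization** (singular-vector / Macenko-style):
  pixel optical densities are projected onto the patch's own two-stain basis,
  the per-stain concentration scale is matched to a reference, and RGB is
  re-rendered in the reference basis.  A channel-statistics (Reinhard-style)
  alternative in CIELAB space is available behind ``method="reinhard"``.
* **Augmentation**: right-angle rotations, horizontal/vertical flips (applied
  identically to image and mask) and mild color jitter (image only).

The built-in reference basis is fitted once to a canonical synthetic tissue
tile rendered in the base H&E basis, so normalizing images that already match
the reference distribution is close to the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from skimage import color as skcolor


@dataclass(frozen=True)
class AugmentPolicy:
    """Geometric and color jitter settings; ranges are symmetric about identity."""

    geometric: bool = True
    color: bool = True
    brightness: float = 0.10
    contrast: float = 0.10
    saturation: float = 0.10
    hue: float = 0.02

    def __post_init__(self) -> None:
        for name in ("brightness", "contrast", "saturation", "hue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} jitter range must be >= 0")


@dataclass(frozen=True)
class StainReference:
    """Reference stain basis and concentration scale for normalization.

    ``stain_matrix`` rows are the hematoxylin and eosin optical-density
    vectors (unit norm); ``max_concentrations`` is the per-stain robust
    maximum (the ``percentile``-th percentile) that source concentrations are
    rescaled to.  ``lab_mean``/``lab_std`` serve the Reinhard-style method.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray
    lab_mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lab_std: np.ndarray = field(default_factory=lambda: np.ones(3))
    percentile: float = 99.0

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("stain_matrix must be 2x3")
        m = m / np.linalg.norm(m, axis=1, keepdims=True)
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(self, "max_concentrations",
                           np.asarray(self.max_concentrations, dtype=float))
        if not (90 < self.percentile <= 100):
            raise ValueError("percentile must lie in (90, 100]")

    @classmethod
    def from_image(cls, image: np.ndarray, percentile: float = 99.0) -> "StainReference":
        """Fit the reference (basis, scale, LAB statistics) to an RGB image."""
        basis, max_c = estimate_stain_basis(image, percentile=percentile)
        lab = skcolor.rgb2lab(np.asarray(image, dtype=np.uint8))
        return cls(stain_matrix=basis, max_concentrations=max_c,
                   lab_mean=lab.reshape(-1, 3).mean(axis=0),
                   lab_std=lab.reshape(-1, 3).std(axis=0) + 1e-8,
                   percentile=percentile)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Optical density per channel, ``-log10((I + 1) / 256)``."""
    return -np.log10((np.asarray(image, dtype=float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(256.0 * np.power(10.0, -od) - 1.0, 0, 255)


class StainEstimationError(RuntimeError):
    """Raised internally when a patch has too little tissue to fit a basis."""


def estimate_stain_basis(
    image: np.ndarray,
    percentile: float = 99.0,
    od_threshold: float = 0.15,
    min_tissue_px: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the two-stain OD basis and robust max concentrations of a patch.

    Singular-vector approach: tissue pixels (total OD above threshold) are
    projected onto their leading 2-D OD plane; the extreme directions at the
    1st/99th angle percentiles give the hematoxylin and eosin vectors
    (hematoxylin = the vector with the larger red-channel OD).
    """
    od = rgb_to_od(image).reshape(-1, 3)
    tissue = od[od.sum(axis=1) > od_threshold]
    if tissue.shape[0] < min_tissue_px:
        raise StainEstimationError(
            f"only {tissue.shape[0]} tissue pixels; cannot estimate a stain basis")
    # leading 2-D plane of the OD cloud
    _, _, vt = np.linalg.svd(tissue - 0.0, full_matrices=False)
    plane = vt[:2]  # 2x3
    # orient plane vectors so projections are mostly positive
    proj = tissue @ plane.T  # Npx x 2
    for j in range(2):
        if np.median(proj[:, j]) < 0:
            plane[j] = -plane[j]
            proj[:, j] = -proj[:, j]
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [100 - percentile, percentile])
    v1 = plane.T @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane.T @ np.array([np.cos(hi), np.sin(hi)])
    basis = np.stack([v1, v2])
    basis = np.clip(basis, 0.0, None)
    basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    if basis[0, 0] < basis[1, 0]:  # hematoxylin carries more red-channel OD
        basis = basis[::-1]
    conc = stain_concentrations(od, basis)
    max_c = np.percentile(conc, percentile, axis=1)
    return basis, np.maximum(max_c, 1e-8)


def stain_concentrations(od_flat: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Least-squares per-pixel stain concentrations (2 x Npx, clipped at 0)."""
    conc, *_ = np.linalg.lstsq(basis.T, od_flat.T, rcond=None)
    return np.clip(conc, 0.0, None)


@lru_cache(maxsize=1)
def default_reference() -> StainReference:
    """Reference fitted to a canonical noise-free synthetic tile in the base basis."""
    from rpcseg.synthetic import CohortSpec, ScannerProfile, generate_roi

    tile = generate_roi(CohortSpec(roi_size=256), ScannerProfile("philips", noise_sd=0.0),
                        seed=20_240_701, case_id="stain_reference")
    return StainReference.from_image(tile.image)


def normalize_patch(
    patch: np.ndarray,
    reference: StainReference | None = None,
    method: str = "macenko",
) -> np.ndarray:
    """Map a patch's color distribution onto the reference stain basis.

    Blank/near-white patches (too few tissue pixels to fit a basis) are
    returned unchanged with a warning.  Output matches the input's shape and
    dtype; label masks are never touched by normalization.
    """
    reference = reference or default_reference()
    img = np.asarray(patch)
    if method == "reinhard":
        return _normalize_reinhard(img, reference)
    if method != "macenko":
        raise ValueError(f"unknown normalization method {method!r}")
    try:
        basis, max_c = estimate_stain_basis(img, percentile=reference.percentile)
    except StainEstimationError as exc:
        warnings.warn(f"patch left unnormalized: {exc}", stacklevel=2)
        return img.copy()
    od = rgb_to_od(img).reshape(-1, 3)
    conc = stain_concentrations(od, basis)
    conc *= (reference.max_concentrations / max_c)[:, None]
    od_out = (conc.T @ reference.stain_matrix).reshape(img.shape)
    out = od_to_rgb(od_out)
    return out.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) else out


def _normalize_reinhard(img: np.ndarray, reference: StainReference) -> np.ndarray:
    lab = skcolor.rgb2lab(img.astype(np.uint8))
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0) + 1e-8
    lab = (lab - mean) / std * reference.lab_std + reference.lab_mean
    out = np.clip(skcolor.lab2rgb(lab) * 255.0, 0, 255)
    return out.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) else out


def augment(
    patch: np.ndarray,
    mask: np.ndarray,
    policy: AugmentPolicy | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform to patch+mask and color jitter to the patch.

    The geometric draw (a right-angle rotation combined with optional flips,
    identity included) permutes pixels only, so the mask's class histogram is
    preserved exactly.  Color jitter perturbs brightness, contrast, saturation
    and hue within the policy's symmetric ranges; jitter steps whose range is
    zero are skipped entirely, leaving pixel values bit-identical.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    policy = policy or AugmentPolicy()
    img, msk = np.asarray(patch), np.asarray(mask)

    if policy.geometric:
        k = int(rng.integers(0, 4))
        flip_h = bool(rng.integers(0, 2))
        flip_v = bool(rng.integers(0, 2))
        img = np.rot90(img, k, axes=(0, 1))
        msk = np.rot90(msk, k, axes=(0, 1))
        if flip_h:
            img, msk = img[:, ::-1], msk[:, ::-1]
        if flip_v:
            img, msk = img[::-1], msk[::-1]

    if policy.color:
        img = _color_jitter(img, policy, rng)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def _color_jitter(img: np.ndarray, policy: AugmentPolicy,
                  rng: np.random.Generator) -> np.ndarray:
    dtype = img.dtype
    out = img.astype(float)
    if policy.brightness > 0:
        out = out * rng.uniform(1 - policy.brightness, 1 + policy.brightness)
    if policy.contrast > 0:
        f = rng.uniform(1 - policy.contrast, 1 + policy.contrast)
        out = (out - out.mean()) * f + out.mean()
    if policy.saturation > 0 or policy.hue > 0:
        hsv = skcolor.rgb2hsv(np.clip(out, 0, 255) / 255.0)
        if policy.hue > 0:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-policy.hue, policy.hue)) % 1.0
        if policy.saturation > 0:
            hsv[..., 1] = np.clip(
                hsv[..., 1] * rng.uniform(1 - policy.saturation, 1 + policy.saturation),
                0, 1)
        out = skcolor.hsv2rgb(hsv) * 255.0
    out = np.clip(out, 0, 255)
    return np.rint(out).astype(dtype) if np.issubdtype(dtype, np.integer) else out
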
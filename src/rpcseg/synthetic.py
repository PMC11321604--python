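"""Synthetic multi-center, multi-scanner H&E-like cohort generator.

Every downstream stage (patch sampling, stain normalization, training,
stitched inference, cross-validation) is exercised on images from this module,
so no slide data needs to be downloaded.  A region of interest is built in two
strictly separated steps:

1. *Geometry* — gland-like structures are placed on a stromal background and
   drive both the ground-truth label mask and two per-pixel stain
   "concentration" planes (hematoxylin and eosin).  Cancerous ducts are
   irregular, jagged, thick-walled rings with dense nuclear stippling; normal
   ducts are smooth thin-walled rings around a clear lumen; other epithelium
   forms clustered blobs; fat is pale circles; stroma is a textured pink
   background.
2. *Scanner rendering* — RGB is composed from the concentration planes by
   Beer-Lambert optical-density mixing of the scanner's two stain vectors,
   followed by per-channel gamma, brightness/contrast offsets and sensor
   noise.  The geometry (and hence the mask) depends only on the geometry
   seed, never on the scanner profile, so the same tissue can be "scanned"
   under different color profiles — the controlled setting for stain
   normalization experiments.

The four built-in profiles emulate the situation where two scanner families
are close in color rendition and the others diverge visibly, the last one
strongly (its gamma and stain basis differ most from the reference).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from rpcseg.taxonomy import (
    BACKGROUND, CANCER, FAT, NORMAL_DUCTS, OTHER_EPITHELIUM,
    AnnotatedROI, CohortManifest, ManifestEntry, write_roi,
)

#: canonical H&E optical-density vectors (rows: hematoxylin, eosin)
BASE_STAIN_MATRIX = np.array(
    [[0.650, 0.704, 0.286],
     [0.072, 0.990, 0.105]]
)
BASE_STAIN_MATRIX /= np.linalg.norm(BASE_STAIN_MATRIX, axis=1, keepdims=True)


class MixtureInfeasibleError(ValueError):
    """Requested class-area mixture cannot be realized at the ROI size."""


@dataclass(frozen=True)
class ScannerProfile:
    """Color rendition of one scanner: stain basis plus tone-curve parameters."""

    name: str
    stain_matrix: np.ndarray = field(default_factory=lambda: BASE_STAIN_MATRIX.copy())
    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brightness: float = 0.0
    contrast: float = 1.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=float)
        if m.shape != (2, 3) or (m < 0).any():
            raise ValueError("stain_matrix must be a non-negative 2x3 array")
        m = m / np.linalg.norm(m, axis=1, keepdims=True)
        object.__setattr__(self, "stain_matrix", m)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rotated_basis(angle_h: float, angle_e: float) -> np.ndarray:
    """Perturb the base H&E basis by mixing each vector toward the other."""
    h, e = BASE_STAIN_MATRIX
    h2 = (1 - angle_h) * h + angle_h * e
    e2 = (1 - angle_e) * e + angle_e * h
    m = np.stack([h2, e2])
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def default_scanner_profiles() -> list[ScannerProfile]:
    """Four profiles: philips (reference), hamamatsu (close), leica (moderate),
    3dhistech (strongly divergent)."""
    return [
        ScannerProfile("philips"),
        ScannerProfile("hamamatsu", stain_matrix=_rotated_basis(0.04, 0.02),
                       gamma=(0.97, 1.00, 1.03), brightness=2.0, noise_sd=2.0),
        ScannerProfile("leica", stain_matrix=_rotated_basis(0.10, 0.06),
                       gamma=(1.07, 0.95, 1.02), brightness=-3.0, noise_sd=2.5),
        ScannerProfile("3dhistech", stain_matrix=_rotated_basis(0.22, 0.16),
                       gamma=(1.25, 0.88, 1.12), brightness=-4.0, noise_sd=2.5),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    ``cases`` lists (center_id, scanner_name, n_cases) triples.
    ``class_mixture`` gives the expected area fraction per foreground target
    class; the remainder is textured stroma background.
    """

    cases: tuple[tuple[str, str, int], ...] = (
        ("center_a", "philips", 6),
        ("center_b", "hamamatsu", 6),
        ("center_c", "leica", 6),
        ("center_d", "3dhistech", 6),
    )
    roi_size: int = 512
    class_mixture: dict[int, float] = field(default_factory=lambda: {
        CANCER: 0.16, NORMAL_DUCTS: 0.10, OTHER_EPITHELIUM: 0.08, FAT: 0.06,
    })
    duct_radius: tuple[float, float] = (11.0, 19.0)
    normal_wall: float = 3.0
    cancer_wall: float = 6.0
    cancer_jaggedness: float = 0.22
    nuclear_dot_density: float = 0.06
    rng_seed: int = 0

    def __post_init__(self) -> None:
        mix = {int(k): float(v) for k, v in self.class_mixture.items()}
        object.__setattr__(self, "class_mixture", mix)
        if any(v < 0 for v in mix.values()):
            raise MixtureInfeasibleError("class mixture fractions must be >= 0")
        if sum(mix.values()) > 0.62:
            # non-overlapping placement cannot pack much beyond this
            raise MixtureInfeasibleError(
                f"total foreground fraction {sum(mix.values()):.2f} infeasible "
                "for non-overlapping placement"
            )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  scale: int = 24) -> np.ndarray:
    """Band-limited noise in [-1, 1] for stromal texture."""
    coarse = rng.standard_normal((max(2, shape[0] // scale), max(2, shape[1] // scale)))
    z = ndimage.zoom(coarse, (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1]),
                     order=1, grid_mode=True, mode="nearest")
    z = z[: shape[0], : shape[1]]
    return np.clip(z / 2.5, -1.0, 1.0)


def _ring_footprint(rng: np.random.Generator, r0: float, wall: float,
                    jagged: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (region, wall, lumen) arrays for one duct, in a local bbox."""
    n_modes = rng.integers(3, 7)
    ks = rng.integers(2, 8, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    amps = rng.uniform(0.3, 1.0, size=n_modes)
    amps *= jagged / max(amps.sum(), 1e-9)

    rmax = r0 * (1 + jagged) + 2
    half = int(np.ceil(rmax))
    yy, xx = np.mgrid[-half: half + 1, -half: half + 1]
    dist = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    mod = np.zeros_like(theta)
    for k, ph, a in zip(ks, phases, amps):
        mod += a * np.sin(k * theta + ph)
    redge = r0 * (1 + mod)
    region = dist <= redge
    lumen = dist <= (redge - wall)
    return region, region & ~lumen, lumen


def _disk(r: float) -> np.ndarray:
    half = int(np.ceil(r))
    yy, xx = np.mgrid[-half: half + 1, -half: half + 1]
    return np.hypot(yy, xx) <= r


def _blob(rng: np.random.Generator, r: float) -> np.ndarray:
    """Cluster of overlapping disks (acinar/islet-like epithelium)."""
    half = int(np.ceil(r * 1.8))
    canvas = np.zeros((2 * half + 1, 2 * half + 1), dtype=bool)
    for _ in range(rng.integers(3, 6)):
        rr = rng.uniform(0.45, 0.75) * r
        cy, cx = rng.uniform(-0.6 * r, 0.6 * r, size=2)
        yy, xx = np.mgrid[-half: half + 1, -half: half + 1]
        canvas |= np.hypot(yy - cy, xx - cx) <= rr
    return canvas


def _place(canvas_occ: np.ndarray, foot: np.ndarray,
           rng: np.random.Generator) -> tuple[int, int] | None:
    """Pick a uniformly random top-left offset where the footprint is disjoint
    from all existing foreground, via FFT cross-correlation of the occupancy
    mask with the footprint; None when no such position exists."""
    from scipy.signal import fftconvolve

    H, W = canvas_occ.shape
    fh, fw = foot.shape
    if fh > H or fw > W:
        return None
    overlap = fftconvolve(canvas_occ.astype(np.float32),
                          foot[::-1, ::-1].astype(np.float32), mode="valid")
    free = np.flatnonzero(overlap < 0.5)
    if free.size == 0:
        return None
    pick = int(free[rng.integers(0, free.size)])
    return divmod(pick, W - fw + 1)


def generate_roi(spec: CohortSpec, scanner: ScannerProfile, seed: int,
                 case_id: str = "synthetic", center_id: str = "") -> AnnotatedROI:
    """Generate one annotated ROI under the given scanner color profile.

    The same ``seed`` always yields bit-identical output; two scanner profiles
    applied to the same seed share an identical mask (geometry) and differ
    only in color rendition.
    """
    n = spec.roi_size
    geom_rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng([seed, zlib.crc32(scanner.name.encode())])

    mask = np.zeros((n, n), dtype=np.uint8)
    # stromal background: pink, lightly textured
    ch = 0.12 + 0.04 * _smooth_noise(geom_rng, (n, n))
    ce = 0.42 + 0.10 * _smooth_noise(geom_rng, (n, n))

    area = float(n * n)
    # structure sizes scale down on small canvases so the requested mixture
    # stays packable without overlap
    scale = min(1.0, n / 256.0)
    r_lo, r_hi = spec.duct_radius[0] * scale, spec.duct_radius[1] * scale
    normal_wall = max(spec.normal_wall * scale, 1.5)
    cancer_wall = max(spec.cancer_wall * scale, 3.0)
    order = [FAT, OTHER_EPITHELIUM, NORMAL_DUCTS, CANCER]
    for cls in order:
        target = spec.class_mixture.get(cls, 0.0)
        if target <= 0:
            continue
        placed = 0
        budget = int(target * area)
        failures = 0
        while placed < budget:
            if cls == FAT:
                foot = _disk(geom_rng.uniform(7 * scale, 14 * scale))
            elif cls == OTHER_EPITHELIUM:
                foot = _blob(geom_rng, geom_rng.uniform(r_lo, r_hi))
            elif cls == NORMAL_DUCTS:
                foot, wall, lumen = _ring_footprint(
                    geom_rng, geom_rng.uniform(r_lo, r_hi),
                    normal_wall, jagged=0.04)
            else:  # CANCER
                foot, wall, lumen = _ring_footprint(
                    geom_rng, geom_rng.uniform(r_lo, r_hi) * 1.1,
                    cancer_wall, jagged=spec.cancer_jaggedness)
            pos = _place(mask != BACKGROUND, foot, geom_rng)
            if pos is None:
                failures += 1
                if failures > 25:
                    raise MixtureInfeasibleError(
                        f"cannot reach fraction {target:.2f} for class {cls} "
                        f"at roi_size {n}"
                    )
                continue
            r, c = pos
            win = (slice(r, r + foot.shape[0]), slice(c, c + foot.shape[1]))
            mask[win][foot] = cls
            if cls == FAT:
                ch[win][foot] = 0.02
                ce[win][foot] = 0.04
            elif cls == OTHER_EPITHELIUM:
                ch[win][foot] = 0.50 + 0.08 * geom_rng.standard_normal()
                ce[win][foot] = 0.48
            elif cls == NORMAL_DUCTS:
                ch[win][wall] = 0.62
                ce[win][wall] = 0.30
                ch[win][lumen] = 0.03
                ce[win][lumen] = 0.05
            else:
                ch[win][wall] = 0.95
                ce[win][wall] = 0.40
                ch[win][lumen] = 0.45
                ce[win][lumen] = 0.35
                # dense nuclear stippling across the whole cancerous region
                dots = geom_rng.random(foot.shape) < spec.nuclear_dot_density
                dots = ndimage.binary_dilation(dots) & foot
                ch[win][dots] = 1.25
            placed += int(foot.sum())

    image = render_scanner(np.stack([ch, ce]), scanner, noise_rng)
    fractions = {int(k): float((mask == k).mean()) for k in
                 (BACKGROUND, NORMAL_DUCTS, CANCER, OTHER_EPITHELIUM, FAT)}
    return AnnotatedROI(image=image, mask=mask, case_id=case_id, center_id=center_id,
                        scanner_type=scanner.name, class_fractions=fractions)


def render_scanner(concentrations: np.ndarray, scanner: ScannerProfile,
                   noise_rng: np.random.Generator | None = None) -> np.ndarray:
    """Render 2xHxW stain concentrations to uint8 RGB under a scanner profile.

    RGB before tone adjustments follows Beer-Lambert transmission
    ``I = 255 * 10**(-(c_h * v_h + c_e * v_e))``.
    """
    od = np.tensordot(concentrations, scanner.stain_matrix, axes=(0, 0))  # HxWx3
    rgb = np.power(10.0, -od)
    rgb = np.power(np.clip(rgb, 1e-6, 1.0), np.asarray(scanner.gamma))
    rgb = (rgb - 0.5) * scanner.contrast + 0.5
    out = rgb * 255.0 + scanner.brightness
    if noise_rng is not None and scanner.noise_sd > 0:
        out = out + noise_rng.normal(0.0, scanner.noise_sd, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_cohort(spec: CohortSpec, profiles: Sequence[ScannerProfile],
                    out_dir: str | Path) -> CohortManifest:
    """Generate the full cohort to ``out_dir`` and return its manifest.

    Per-case geometry seeds are ``spec.rng_seed + case_index`` so the cohort is
    reproducible and cases are independent.  Writes ``images/``, ``masks/``,
    ``manifest.csv`` and a ``fractions.csv`` with the realized per-class area
    fractions of every ROI.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 scanner profiles for cross-validation cohorts")
    by_name = {p.name: p for p in profiles}
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    entries: list[ManifestEntry] = []
    frac_rows = []
    idx = 0
    for center_id, scanner_name, n_cases in spec.cases:
        if scanner_name not in by_name:
            raise ValueError(f"no profile for scanner {scanner_name!r}")
        for j in range(n_cases):
            case_id = f"{scanner_name}_{center_id}_{j:03d}"
            roi = generate_roi(spec, by_name[scanner_name], seed=spec.rng_seed + idx,
                               case_id=case_id, center_id=center_id)
            img_rel = f"images/{case_id}.png"
            msk_rel = f"masks/{case_id}.png"
            write_roi(roi, out / img_rel, out / msk_rel)
            entries.append(ManifestEntry(case_id, center_id, scanner_name,
                                         img_rel, msk_rel))
            frac_rows.append({"case_id": case_id, **{
                f"frac_{k}": v for k, v in (roi.class_fractions or {}).items()}})
            idx += 1
    manifest = CohortManifest(entries)
    manifest.to_csv(out / "manifest.csv")
    pd.DataFrame(frac_rows).to_csv(out / "fractions.csv", index=False)
    return manifest
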
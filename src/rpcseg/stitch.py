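"""Whole-ROI prediction by overlapping sliding windows with weighted stitching.

Patches are predicted on a stride-256 grid of 512px windows (defaults), with
the final row and column of anchors clamped to the ROI border so every pixel
is covered.  Per-pixel class scores are blended as a weighted average with a
separable raised-cosine window that peaks at the patch center and stays above
a small floor at the edges — agreeing predictions pass through unchanged
(conservation) while seams between patches are suppressed.  ROIs smaller than
one patch are reflectively padded for inference only.

The label at each pixel is the argmax over the five averaged score planes,
ties resolved toward the lowest class code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from rpcseg.taxonomy import IGNORE, TARGET_CODES, TARGET_LABELS


class ScoreModel(Protocol):
    """Anything that maps an RGB patch to (P, P, n_classes) class scores."""

    def predict_scores(self, patch: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class StitchSpec:
    """Window geometry and blending kernel for stitched inference."""

    patch_size: int = 512
    stride: int = 256
    kernel_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.stride > self.patch_size:
            raise ValueError("stride must not exceed patch_size")
        if not (0 < self.kernel_floor <= 1):
            raise ValueError("kernel_floor must lie in (0, 1]")

    def kernel(self) -> np.ndarray:
        """Separable raised-cosine (Hann) window, floored at ``kernel_floor``."""
        i = np.arange(self.patch_size)
        h = np.sin(np.pi * (i + 0.5) / self.patch_size) ** 2
        h = np.maximum(h, self.kernel_floor)
        return np.outer(h, h)


@dataclass
class StitchedPrediction:
    """Averaged per-class score planes, the argmax label mask, and coverage weights."""

    scores: np.ndarray       # H x W x n_classes
    labels: np.ndarray       # H x W target codes
    weight_plane: np.ndarray  # H x W accumulated kernel weight

    def class_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=max(TARGET_CODES) + 1)
        return {c: int(counts[c]) for c in TARGET_CODES}


def inference_anchors(extent: int, spec: StitchSpec) -> list[int]:
    """1-D anchor positions covering [0, extent) fully; last anchor clamped."""
    last = extent - spec.patch_size
    xs = list(range(0, max(last, 0) + 1, spec.stride))
    if xs[-1] != last and last > 0:
        xs.append(last)
    return xs


def predict_roi(model: ScoreModel, image: np.ndarray,
                spec: StitchSpec | None = None) -> StitchedPrediction:
    """Predict class scores for a whole ROI by weighted sliding-window stitching.

    Every pixel's final score per class is
    ``sum(kernel * patch_score) / sum(kernel)`` over the patches covering it.
    The output is invariant to patch visit order, and if all covering patches
    agree at a pixel the averaged score equals that common value exactly.
    """
    spec = spec or StitchSpec()
    P = spec.patch_size
    H, W = image.shape[:2]
    pad_h, pad_w = max(P - H, 0), max(P - W, 0)
    padded = image
    if pad_h or pad_w:
        padded = np.pad(image, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    Hp, Wp = padded.shape[:2]

    kernel = spec.kernel()
    first = model.predict_scores(padded[:P, :P])
    n_classes = first.shape[-1]
    acc = np.zeros((Hp, Wp, n_classes), dtype=np.float64)
    wacc = np.zeros((Hp, Wp), dtype=np.float64)

    for y in inference_anchors(Hp, spec):
        for x in inference_anchors(Wp, spec):
            scores = first if (y == 0 and x == 0) else \
                model.predict_scores(padded[y: y + P, x: x + P])
            if scores.shape[-1] != n_classes:
                raise ValueError(
                    f"model emitted {scores.shape[-1]} channels, expected {n_classes}")
            acc[y: y + P, x: x + P] += kernel[..., None] * scores
            wacc[y: y + P, x: x + P] += kernel

    scores = acc / wacc[..., None]
    scores = scores[:H, :W]
    wacc = wacc[:H, :W]
    labels = scores.argmax(axis=2).astype(np.uint8)  # ties -> lowest class code
    return StitchedPrediction(scores=scores, labels=labels, weight_plane=wacc)


# ---------------------------------------------------------------------------
# rendering and pixel accounting
# ---------------------------------------------------------------------------

#: display palette: cancer red, normal ducts green, other tissue orange,
#: fat pale yellow, background black, uncertain white
PALETTE: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    1: (0, 160, 0),
    2: (220, 0, 0),
    3: (255, 140, 0),
    4: (255, 255, 160),
    IGNORE: (255, 255, 255),
}


def render_rgb(labels: np.ndarray | StitchedPrediction,
               palette: dict[int, tuple[int, int, int]] | None = None) -> np.ndarray:
    """Render a label mask to the fixed RGB overlay palette."""
    if isinstance(labels, StitchedPrediction):
        labels = labels.labels
    palette = palette or PALETTE
    lut = np.zeros((256, 3), dtype=np.uint8)
    for code, rgb in palette.items():
        lut[code] = rgb
    return lut[np.asarray(labels, dtype=np.uint8)]


def rgb_to_labels(image: np.ndarray,
                  palette: dict[int, tuple[int, int, int]] | None = None) -> np.ndarray:
    """Invert :func:`render_rgb`; the palette round trip is lossless."""
    palette = palette or PALETTE
    inv = {tuple(v): k for k, v in palette.items()}
    flat = image.reshape(-1, 3)
    out = np.empty(flat.shape[0], dtype=np.uint8)
    colors, idx = np.unique(flat, axis=0, return_inverse=True)
    codes = np.array([inv[tuple(c)] for c in colors.tolist()], dtype=np.uint8)
    out = codes[idx]
    return out.reshape(image.shape[:2])


def count_rpc_pixels(prediction: StitchedPrediction | np.ndarray) -> dict:
    """Exact per-class pixel histogram; RPC = the cancer-class count.

    Residual pancreatic cancer burden is quantified as the number of pixels
    the model (or the pathologist's mask) designates as cancer.
    """
    labels = prediction.labels if isinstance(prediction, StitchedPrediction) else prediction
    counts = np.bincount(np.asarray(labels, dtype=np.uint8).ravel(), minlength=256)
    out = {TARGET_LABELS[c]: int(counts[c]) for c in TARGET_CODES}
    out["ignore"] = int(counts[IGNORE])
    out["rpc"] = out["cancer"]
    return out


def counts_to_csv(per_roi_counts: dict[str, dict], path: str | Path) -> None:
    """Write a per-ROI class-count table (one row per ROI)."""
    pd.DataFrame.from_dict(per_roi_counts, orient="index").rename_axis("roi_id").to_csv(path)
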
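"""Balanced training-patch sampling from annotated ROIs.

Training patches are cut from each ROI on a sliding grid of 512x512 windows
with 50% overlap (stride 256).  A window enters the data set only if at least
one foreground segmentation class (normal ducts, cancer, other epithelium,
fat) covers at least 10% of its area; background/stroma and ignore pixels do
not qualify a patch.  To limit class imbalance, at most 50 patches per class
are kept for each case, subsampled uniformly at random with a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rpcseg.taxonomy import FOREGROUND_CODES


@dataclass(frozen=True)
class PatchSpec:
    """Sliding-window geometry and balancing rules for training patches."""

    patch_size: int = 512
    train_stride: int = 256
    inclusion_fraction: float = 0.10
    per_case_class_cap: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.inclusion_fraction <= 1):
            raise ValueError("inclusion_fraction must lie in (0, 1]")
        if self.train_stride > self.patch_size:
            raise ValueError("stride must not exceed patch_size")
        if self.per_case_class_cap < 1:
            raise ValueError("per-case class cap must be >= 1")


@dataclass(frozen=True)
class PatchRecord:
    """One retained patch: top-left anchor plus its qualifying classes."""

    case_id: str
    roi_id: str
    y: int
    x: int
    classes: tuple[int, ...]


@dataclass
class PatchSet:
    """Balanced patch inventory with per-case class tallies."""

    records: list[PatchRecord]
    spec: PatchSpec = field(default_factory=PatchSpec)
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def class_tally(self) -> dict[tuple[str, int], int]:
        """(case_id, class) -> number of retained patches tagged with that class."""
        tally: dict[tuple[str, int], int] = {}
        for rec in self.records:
            for cls in rec.classes:
                key = (rec.case_id, cls)
                tally[key] = tally.get(key, 0) + 1
        return tally

    def to_csv(self, path: str | Path) -> None:
        rows = [{"case_id": r.case_id, "roi_id": r.roi_id, "y": r.y, "x": r.x,
                 "classes": "|".join(map(str, r.classes))} for r in self.records]
        pd.DataFrame(rows, columns=["case_id", "roi_id", "y", "x", "classes"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, spec: PatchSpec | None = None) -> "PatchSet":
        df = pd.read_csv(path, dtype={"case_id": str, "roi_id": str})
        recs = [PatchRecord(r.case_id, r.roi_id, int(r.y), int(r.x),
                            tuple(int(c) for c in str(r.classes).split("|") if c != ""))
                for r in df.itertuples(index=False)]
        return cls(records=recs, spec=spec or PatchSpec())


def enumerate_anchors(roi_shape: tuple[int, int], spec: PatchSpec) -> list[tuple[int, int]]:
    """Top-left (y, x) anchors of all fully-contained sliding windows, row-major.

    The anchor grid is ``(i*stride, j*stride)`` for every position where the
    whole patch fits inside the ROI; ROIs smaller than one patch yield no
    anchors (with a warning) — borders are not padded at training time.
    """
    H, W = roi_shape[:2]
    P, s = spec.patch_size, spec.train_stride
    if H < P or W < P:
        warnings.warn(
            f"ROI {H}x{W} smaller than patch size {P}; no training patches",
            stacklevel=2,
        )
        return []
    return [(i * s, j * s)
            for i in range((H - P) // s + 1)
            for j in range((W - P) // s + 1)]


def qualifying_classes(mask_window: np.ndarray, spec: PatchSpec) -> tuple[int, ...]:
    """Foreground classes covering >= inclusion_fraction of the window area."""
    area = mask_window.shape[0] * mask_window.shape[1]
    threshold = spec.inclusion_fraction * area
    counts = np.bincount(mask_window.ravel(), minlength=256)
    return tuple(c for c in FOREGROUND_CODES if counts[c] >= threshold)


def filter_by_content(
    anchors: Iterable[tuple[int, int]],
    mask: np.ndarray,
    spec: PatchSpec,
    case_id: str = "",
    roi_id: str = "",
) -> list[PatchRecord]:
    """Keep anchors whose window holds >= 10% of some foreground class.

    The threshold is inclusive and counts only the four foreground target
    classes against the full patch area; stroma/background and ignore pixels
    never qualify a patch.  Each retained record is tagged with *all*
    qualifying classes.
    """
    out = []
    P = spec.patch_size
    for y, x in anchors:
        classes = qualifying_classes(mask[y: y + P, x: x + P], spec)
        if classes:
            out.append(PatchRecord(case_id=case_id, roi_id=roi_id or case_id,
                                   y=y, x=x, classes=classes))
    return out


def apply_cap(records: Sequence[PatchRecord], spec: PatchSpec, seed: int = 0) -> PatchSet:
    """Enforce the per-case, per-class patch cap by seeded uniform subsampling.

    For every (case, class) with more tagged patches than the cap, a uniform
    random subset of exactly ``cap`` patches is retained for that class.  A
    patch kept for any of its classes is kept once.
    """
    rng = np.random.default_rng(seed)
    # records grouped per (case, class), preserving order for determinism
    groups: dict[tuple[str, int], list[int]] = {}
    for i, rec in enumerate(records):
        for cls in rec.classes:
            groups.setdefault((rec.case_id, cls), []).append(i)

    kept_for: dict[int, set[int]] = {i: set() for i in range(len(records))}
    for (case_id, cls) in sorted(groups):
        idxs = groups[(case_id, cls)]
        if len(idxs) > spec.per_case_class_cap:
            chosen = rng.choice(len(idxs), size=spec.per_case_class_cap, replace=False)
            idxs = [idxs[k] for k in sorted(chosen)]
        for i in idxs:
            kept_for[i].add(cls)

    final = [
        PatchRecord(rec.case_id, rec.roi_id, rec.y, rec.x,
                    tuple(sorted(kept_for[i])))
        for i, rec in enumerate(records) if kept_for[i]
    ]
    return PatchSet(records=final, spec=spec, rng_seed=seed)


def build_patchset(
    masks: Mapping[str, np.ndarray],
    spec: PatchSpec | None = None,
    seed: int = 0,
    case_of: Mapping[str, str] | None = None,
) -> PatchSet:
    """End-to-end sampling: enumerate, content-filter and cap patches.

    ``masks`` maps roi_id -> label mask; ``case_of`` maps roi_id -> case_id
    (identity when omitted, i.e. one ROI per case).
    """
    spec = spec or PatchSpec()
    records: list[PatchRecord] = []
    for roi_id in sorted(masks):
        mask = masks[roi_id]
        case_id = (case_of or {}).get(roi_id, roi_id)
        anchors = enumerate_anchors(mask.shape, spec)
        records.extend(filter_by_content(anchors, mask, spec,
                                         case_id=case_id, roi_id=roi_id))
    return apply_cap(records, spec, seed=seed)
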
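"""Training of the encoder-decoder segmentation model on a balanced patch set.

The model predicts five per-pixel channels (background plus the four
foreground classes) through independent sigmoids trained with per-channel
binary cross-entropy on one-hot targets; pixels labeled "uncertain" carry
zero loss weight.  Optimization uses Adam, runs for at most ``max_epochs``
epochs, and halts early when the validation loss has not improved for
``early_stop_patience`` consecutive epochs, returning the weights of the best
epoch.  The validation split is drawn at *case* level (never patch level) so
overlapping patches of one ROI cannot leak across the split.

Stain normalization (when enabled) is applied to every patch before
augmentation, at training and at inference time alike.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rpcseg.nn import Adam, NetConfig, SmallUNet, bce_with_logits, preprocess, sigmoid
from rpcseg.patches import PatchRecord, PatchSet
from rpcseg.stains import AugmentPolicy, StainReference, augment, normalize_patch
from rpcseg.taxonomy import IGNORE, TARGET_CODES, AnnotatedROI


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    ``encoder`` names the network family and width, e.g. ``small_unet_16``
    (a compact two-level U-Net with base width 16); widths are configurable
    so tests can run a narrow variant on a CPU.
    """

    encoder: str = "small_unet_16"
    n_classes: int = 5
    patch_size: int = 512
    learning_rate: float = 1e-4
    max_epochs: int = 30
    early_stop_patience: int = 7
    batch_size: int = 8
    seed: int = 0
    val_fraction: float = 0.2
    normalize: bool = True
    augment: bool = True
    augment_policy: AugmentPolicy = field(default_factory=AugmentPolicy)
    stain_method: str = "macenko"

    def __post_init__(self) -> None:
        if not self.early_stop_patience < self.max_epochs and self.max_epochs > 1:
            raise ValueError("early_stop_patience must be < max_epochs")
        if not (0 < self.val_fraction <= 0.5):
            raise ValueError("val_fraction must lie in (0, 0.5]")

    def base_channels(self) -> int:
        prefix = "small_unet_"
        if not self.encoder.startswith(prefix):
            raise ValueError(f"unknown encoder {self.encoder!r}; expected 'small_unet_<width>'")
        return int(self.encoder[len(prefix):])


def make_targets(mask: np.ndarray, n_classes: int = 5,
                 ignore_code: int = IGNORE) -> tuple[np.ndarray, np.ndarray]:
    """One-hot target planes plus the ignore-weight plane for one mask.

    Returns ``(targets, weights)`` with shapes (H, W, n_classes) and
    (H, W, 1); background is an explicit channel, and every pixel equal to
    ``ignore_code`` gets weight 0.  Codes outside the taxonomy raise.
    """
    mask = np.asarray(mask)
    valid = set(TARGET_CODES) | {ignore_code}
    present = set(np.unique(mask).tolist())
    if not present <= valid:
        raise ValueError(f"mask holds unexpected codes {sorted(present - valid)}")
    targets = np.zeros(mask.shape + (n_classes,), dtype=np.float32)
    for c in range(n_classes):
        targets[..., c] = mask == c
    weights = (mask != ignore_code).astype(np.float32)[..., None]
    return targets, weights


class EarlyStopper:
    """Track the best validation loss; signal a stop after ``patience`` stalls."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self._stale = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record epoch (1-based); return True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self._stale = 0
        else:
            self._stale += 1
        return self._stale >= self.patience


@dataclass
class TrainedModel:
    """A trained network with its stain reference, history and config snapshot."""

    net: SmallUNet
    config: TrainConfig
    history: list[dict]
    best_epoch: int
    stain_reference: StainReference | None = None

    def predict_scores(self, patch: np.ndarray) -> np.ndarray:
        """Per-class sigmoid scores for one RGB patch, normalized like training."""
        if self.config.normalize:
            patch = normalize_patch(patch, self.stain_reference,
                                    method=self.config.stain_method)
        return self.net.predict_scores(patch)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.net.save(path)
        meta = {"config": {**asdict(self.config),
                           "augment_policy": asdict(self.config.augment_policy)},
                "best_epoch": self.best_epoch}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
        pd.DataFrame(self.history).to_csv(path.with_suffix(".history.csv"), index=False)


def _case_split(case_ids: Sequence[str], val_fraction: float,
                rng: np.random.Generator) -> tuple[set[str], set[str]]:
    cases = sorted(set(case_ids))
    if len(cases) < 2:
        raise ValueError("need >= 2 cases for a case-level validation split")
    n_val = max(1, int(round(val_fraction * len(cases))))
    order = rng.permutation(len(cases))
    val = {cases[i] for i in order[:n_val]}
    return set(cases) - val, val


def _extract(records: Sequence[PatchRecord], rois: Mapping[str, AnnotatedROI],
             config: TrainConfig,
             reference: StainReference | None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut (image, mask) windows for records; stain-normalize images once."""
    out = []
    P = config.patch_size
    for rec in records:
        roi = rois[rec.roi_id]
        img = roi.image[rec.y: rec.y + P, rec.x: rec.x + P]
        msk = roi.mask[rec.y: rec.y + P, rec.x: rec.x + P]
        if config.normalize:
            img = normalize_patch(img, reference, method=config.stain_method)
        out.append((np.ascontiguousarray(img), np.ascontiguousarray(msk)))
    return out


def _epoch_pass(net: SmallUNet, optimizer: Adam | None,
                samples: list[tuple[np.ndarray, np.ndarray]],
                config: TrainConfig, rng: np.random.Generator | None) -> float:
    """One pass over samples; trains when an optimizer is given, else evaluates."""
    n = len(samples)
    order = rng.permutation(n) if (optimizer is not None and rng is not None) \
        else np.arange(n)
    total, total_w = 0.0, 0
    for start in range(0, n, config.batch_size):
        batch_idx = order[start: start + config.batch_size]
        xs, ts, ws = [], [], []
        for i in batch_idx:
            img, msk = samples[i]
            if optimizer is not None and config.augment:
                img, msk = augment(img, msk, config.augment_policy, rng)
            t, w = make_targets(msk, config.n_classes)
            xs.append(preprocess(img, net.config.dtype))
            ts.append(t)
            ws.append(w)
        x = np.stack(xs)
        logits, cache = net.forward(x)
        loss, dz = bce_with_logits(logits, np.stack(ts), np.stack(ws))
        if optimizer is not None:
            grads = net.backward(dz, cache)
            optimizer.step(grads)
        total += loss * len(batch_idx)
        total_w += len(batch_idx)
    return total / max(total_w, 1)


def train(patchset: PatchSet, rois: Mapping[str, AnnotatedROI],
          config: TrainConfig | None = None,
          stain_reference: StainReference | None = None) -> TrainedModel:
    """Train the segmentation network on a balanced patch set.

    ``rois`` maps roi_id to the loaded :class:`AnnotatedROI`.  Stops at
    ``max_epochs`` or once validation loss has stalled for
    ``early_stop_patience`` epochs; the returned model carries the weights of
    the best validation epoch and the full per-epoch loss history.
    """
    config = config or TrainConfig()
    if len(patchset) == 0:
        raise ValueError("patch set is empty")
    split_rng = np.random.default_rng([config.seed, 0x5EED])
    train_cases, val_cases = _case_split([r.case_id for r in patchset.records],
                                         config.val_fraction, split_rng)
    train_recs = [r for r in patchset.records if r.case_id in train_cases]
    val_recs = [r for r in patchset.records if r.case_id in val_cases]
    if not val_recs:
        raise ValueError("validation split holds no patches")
    present = {c for r in train_recs for c in r.classes}
    if present < {1, 2, 3, 4}:
        import warnings
        warnings.warn(f"training patches miss foreground classes {sorted({1,2,3,4}-present)}",
                      stacklevel=2)

    train_samples = _extract(train_recs, rois, config, stain_reference)
    val_samples = _extract(val_recs, rois, config, stain_reference)

    net = SmallUNet(NetConfig(base_channels=config.base_channels(),
                              n_classes=config.n_classes), seed=config.seed)
    optimizer = Adam(net.params, lr=config.learning_rate)
    stopper = EarlyStopper(config.early_stop_patience)
    best_params = copy.deepcopy(net.params)
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        epoch_rng = np.random.default_rng([config.seed, epoch])
        train_loss = _epoch_pass(net, optimizer, train_samples, config, epoch_rng)
        val_loss = _epoch_pass(net, None, val_samples, config, None)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_params = copy.deepcopy(net.params)
        if stop:
            break

    net.params = best_params
    optimizer.params = net.params
    return TrainedModel(net=net, config=config, history=history,
                        best_epoch=stopper.best_epoch, stain_reference=stain_reference)
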
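"""Training loop, augmentation, plateau stopping and k-fold cross-validation.

Training minimizes the class-weighted softmax cross-entropy (weights
0.2 non-valve / 0.8 valve by default, countering the heavy class imbalance
of small valve ROIs) with RMSProp.  Augmentation at batch time applies a
shared geometric transform (random zoom, rotation, crop, horizontal and
vertical flips) to the image and its mask — the mask through
nearest-neighbor resampling and re-binarization — plus Gaussian noise on
the image alone.  Progress is monitored by the training-set Dice
coefficient computed on non-augmented images; training stops when Dice
stops improving (plateau) or at the epoch cap.  All randomness flows from
a single seed, so identical config reproduces identical parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import PCSeries, SegmentationMap
from .metrics import MetricReport, evaluate_case, summarize
from .model import (
    GeometryRecord,
    ModelConfig,
    ResidualUNet,
    inverse_map_masks,
    preprocess,
    segment,
)
from .nn import RMSProp, weighted_softmax_ce

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "DivergenceError",
    "weighted_ce_loss",
    "augment",
    "train",
    "make_folds",
    "cross_validate",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; every stochastic choice derives from seed."""

    class_weights: tuple[float, float] = (0.2, 0.8)  # (non-valve, valve)
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 200
    plateau_patience: int = 10
    plateau_delta: float = 0.002
    crop_size: int = 224
    zoom_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: float = 15.0
    flip_probability: float = 0.5
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.class_weights):
            raise ValueError(f"class weights must be nonnegative: {self.class_weights}")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")

    @classmethod
    def reduced(cls, **overrides) -> "TrainConfig":
        """Desk-scale profile matching ModelConfig.reduced (64x64 inputs)."""
        base = cls(crop_size=56, batch_size=8)
        return replace(base, **overrides)


@dataclass(frozen=True)
class FoldPlan:
    """Case-id -> fold-index assignment for k-fold cross-validation."""

    fold_assignments: dict[str, int]
    k: int

    def fold_cases(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.fold_assignments.items() if f == fold)

    def train_cases(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.fold_assignments.items() if f != fold)


def weighted_ce_loss(
    logits: np.ndarray,
    truth: SegmentationMap | np.ndarray,
    class_weights: Sequence[float] = (0.2, 0.8),
) -> float:
    """Class-weighted cross-entropy averaged over pixels and frames.

    ``logits`` is (N, 2, H, W); ``truth`` a binary mask stack (N, H, W).
    """
    t = truth.masks if isinstance(truth, SegmentationMap) else np.asarray(truth)
    loss, _ = weighted_softmax_ce(logits, t, np.asarray(class_weights, dtype=float))
    return loss


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One random augmentation of an (image, mask) pair.

    Identical geometric transform for both; the mask is resampled
    nearest-neighbor and re-binarized; Gaussian noise goes on the image
    only.  Output spatial size is ``cfg.crop_size``.
    """
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} must align")
    h, w = image.shape
    if cfg.crop_size > min(h, w):
        raise ValueError(f"crop_size {cfg.crop_size} exceeds input size {image.shape}")
    img = image.astype(np.float32)
    msk = mask.astype(np.uint8)

    lo, hi = cfg.zoom_range
    factor = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    if factor != 1.0:
        img = _zoom_keep_shape(img, factor, order=1)
        msk = _zoom_keep_shape(msk, factor, order=0)

    if cfg.rotation_range_deg > 0:
        angle = float(rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant")

    top = int(rng.integers(0, h - cfg.crop_size + 1))
    left = int(rng.integers(0, w - cfg.crop_size + 1))
    img = img[top : top + cfg.crop_size, left : left + cfg.crop_size]
    msk = msk[top : top + cfg.crop_size, left : left + cfg.crop_size]

    if rng.random() < cfg.flip_probability:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < cfg.flip_probability:
        img, msk = img[::-1, :], msk[::-1, :]

    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape).astype(np.float32)

    return np.ascontiguousarray(img), np.ascontiguousarray((msk > 0).astype(np.uint8))


def _zoom_keep_shape(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom about the center, then crop/pad back to the original shape."""
    h, w = arr.shape
    zoomed = ndimage.zoom(arr, factor, order=order)
    zh, zw = zoomed.shape
    out = np.zeros_like(arr, shape=(h, w))
    if zh >= h:
        t = (zh - h) // 2
        l = (zw - w) // 2
        out[...] = zoomed[t : t + h, l : l + w]
    else:
        t = (h - zh) // 2
        l = (w - zw) // 2
        out[t : t + zh, l : l + zw] = zoomed
    return out


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------

def _mask_to_grid(masks: np.ndarray, geom: GeometryRecord) -> np.ndarray:
    """Forward-map native masks onto the padded working grid (nearest)."""
    out = np.zeros((masks.shape[0], geom.target, geom.target), dtype=np.uint8)
    for n, frame in enumerate(masks):
        if geom.zoom != 1.0:
            frame = ndimage.zoom(frame.astype(np.uint8), geom.zoom, order=0)
            frame = frame[: geom.resampled_shape[0], : geom.resampled_shape[1]]
        rh, rw = frame.shape
        out[n, geom.pad_top : geom.pad_top + rh, geom.pad_left : geom.pad_left + rw] = frame
    return out


def _flatten_dataset(
    dataset: Sequence[tuple[PCSeries, SegmentationMap]],
    input_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every exam and stack all frames into flat training arrays."""
    images, masks = [], []
    for series, seg in dataset:
        seg.check_matches(series)
        frames, geom = preprocess(series, target=input_size)
        images.append(frames)
        masks.append(_mask_to_grid(seg.masks, geom))
    return np.concatenate(images), np.concatenate(masks)


def _pooled_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = int((pred.astype(bool) & truth.astype(bool)).sum())
    total = int(pred.sum()) + int(truth.sum())
    return 1.0 if total == 0 else 2.0 * inter / total


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(
    dataset: Sequence[tuple[PCSeries, SegmentationMap]],
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    history_path: str | Path | None = None,
) -> tuple[ResidualUNet, list[dict]]:
    """Train a residual U-net with RMSProp and Dice-plateau stopping.

    Per-epoch training Dice is computed on the non-augmented training
    images with the same argmax rule used at inference.  Training stops
    when Dice has not improved by at least ``plateau_delta`` for
    ``plateau_patience`` consecutive epochs, or at ``max_epochs``.  The
    returned model carries the best-Dice epoch's parameters.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    images, masks = _flatten_dataset(dataset, model_cfg.input_size)
    if cfg.crop_size > model_cfg.input_size:
        raise ValueError(
            f"crop_size {cfg.crop_size} exceeds model input {model_cfg.input_size}"
        )
    div = 2 ** (model_cfg.depth - 1)
    if cfg.crop_size % div != 0:
        raise ValueError(f"crop_size {cfg.crop_size} must be divisible by {div}")

    model = ResidualUNet(model_cfg, seed=cfg.seed)
    opt = RMSProp(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    w = np.asarray(cfg.class_weights, dtype=float)

    n_frames = images.shape[0]
    history: list[dict] = []
    best_dice = -np.inf
    best_state = model.state_dict()
    stall = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_frames)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_frames, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_img = np.empty((len(idx), cfg.crop_size, cfg.crop_size), dtype=np.float32)
            batch_msk = np.empty((len(idx), cfg.crop_size, cfg.crop_size), dtype=np.uint8)
            for j, i in enumerate(idx):
                batch_img[j], batch_msk[j] = augment(images[i], masks[i], cfg, rng)
            logits = model.forward(batch_img[:, None], train=True)
            loss, dlogits = weighted_softmax_ce(logits, batch_msk, w)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1

        pred = np.argmax(model.predict_logits(images, batch_size=cfg.batch_size), axis=1)
        train_dice = _pooled_dice(pred, masks)
        history.append(
            {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "train_dice": train_dice}
        )
        logger.info("epoch %d: loss %.4f, train Dice %.4f", epoch, history[-1]["loss"], train_dice)

        if train_dice > best_dice + cfg.plateau_delta:
            best_dice = train_dice
            best_state = model.state_dict()
            stall = 0
        else:
            if train_dice > best_dice:
                best_dice = train_dice
                best_state = model.state_dict()
            stall += 1
            if stall > cfg.plateau_patience:
                logger.info("training Dice plateau at epoch %d; stopping", epoch)
                break

    model.load_state_dict(best_state)
    if history_path is not None:
        import pandas as pd

        pd.DataFrame(history).to_csv(Path(history_path), index=False)
    return model, history


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(case_ids: Sequence[str], k: int = 6, seed: int = 0) -> FoldPlan:
    """Random, seeded, balanced partition into k non-overlapping folds.

    Fold sizes differ by at most one (round-robin deal of a shuffled
    ordering).  150 cases with k=6 yields six folds of 25.
    """
    ids = sorted(set(case_ids))
    if len(ids) != len(list(case_ids)):
        raise ValueError("case ids must be unique")
    if len(ids) < k:
        raise ValueError(f"need at least {k} cases for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return FoldPlan({case: i % k for i, case in enumerate(order)}, k=k)


def cross_validate(
    dataset: dict[str, tuple[PCSeries, SegmentationMap]],
    plan: FoldPlan,
    cfg: TrainConfig,
    model_cfg: ModelConfig,
) -> dict:
    """Train one model per fold on the complement; evaluate held-out cases.

    Returns per-case :class:`MetricReport` objects (each case appears in
    exactly one test set, never in its own training set), a summary with
    nonparametric bootstrap CIs over per-case metrics, and the per-fold
    trained models.
    """
    missing = set(plan.fold_assignments) - set(dataset)
    if missing:
        raise ValueError(f"plan covers unknown cases: {sorted(missing)}")
    uncovered = set(dataset) - set(plan.fold_assignments)
    if uncovered:
        raise ValueError(f"plan does not cover cases: {sorted(uncovered)}")

    reports: list[MetricReport] = []
    models: list[ResidualUNet] = []
    for fold in range(plan.k):
        train_ids = plan.train_cases(fold)
        test_ids = plan.fold_cases(fold)
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        model, _ = train([dataset[c] for c in train_ids], fold_cfg, model_cfg)
        models.append(model)
        for case in test_ids:
            series, truth = dataset[case]
            pred = segment(series, model)
            reports.append(
                evaluate_case(pred, truth, series.pixel_spacing_mm, case_id=case)
            )
    reports.sort(key=lambda r: r.per_case_id)
    return {
        "reports": reports,
        "summary": summarize(reports, seed=cfg.seed),
        "models": models,
    }
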
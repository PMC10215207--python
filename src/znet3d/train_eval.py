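"""Training, prediction and dice evaluation.

Training uses ADAM on a binary cross-entropy loss over the three
overlapping binary mask channels (batch size 1 by default).  Evaluation
binarizes the sigmoid outputs at a threshold and scores each region with
the dice coefficient 2|MS∩GT| / (|MS|+|GT|).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import Adam
from .preprocessing import MASK_CHANNELS, MaskStack, ModalityStack
from .znet_model import Znet

log = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 1
    learning_rate: float = 1e-4
    train_fraction: float = 0.8
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_dice: List[Dict[str, float]] = field(default_factory=list)
    best_epoch: Optional[int] = None


@dataclass
class DiceReport:
    """Per-case and aggregate dice values for the three regions."""

    per_case: List[Dict[str, float]]
    region_means: Dict[str, float]
    overall_mean: float

    @staticmethod
    def from_per_case(per_case: List[Dict[str, float]]) -> "DiceReport":
        region_means = {
            region: float(np.mean([c[region] for c in per_case]))
            for region in MASK_CHANNELS
        }
        overall = float(np.mean([region_means[r] for r in MASK_CHANNELS]))
        return DiceReport(per_case=per_case, region_means=region_means,
                          overall_mean=overall)


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy over all channels and voxels."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def dice_coefficient(ms: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity 2|MS∩GT| / (|MS|+|GT|); defined as 1.0 for two
    empty masks (perfect agreement on the absence of the region)."""
    ms = np.asarray(ms)
    gt = np.asarray(gt)
    if ms.shape != gt.shape:
        raise ValueError(f"shape mismatch: {ms.shape} vs {gt.shape}")
    ms = ms.astype(bool)
    gt = gt.astype(bool)
    total = int(ms.sum()) + int(gt.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(ms, gt).sum()) / total


def predict_case(model: Znet, stack: ModalityStack, threshold: float = 0.5) -> MaskStack:
    """Forward one case (eval mode) and binarize each channel at ``threshold``."""
    x = stack.data[None].astype(np.float32)
    probs = model.forward(x, train=False)[0]
    data = (probs >= threshold).astype(np.uint8)
    return MaskStack(data=data, case_id=stack.case_id)


def _case_dice(pred: MaskStack, gt: MaskStack) -> Dict[str, float]:
    scores = {
        region: dice_coefficient(pred.data[i], gt.data[i])
        for i, region in enumerate(MASK_CHANNELS)
    }
    scores["case_id"] = gt.case_id
    return scores


def evaluate_dataset(
    model: Znet,
    cases: Sequence[Tuple[ModalityStack, MaskStack]],
    config: TrainConfig = None,
) -> DiceReport:
    """Score every case with ground truth; aggregate per-region means and the
    overall mean (arithmetic mean of the three region means)."""
    if not cases:
        raise ValueError("cannot evaluate an empty case list")
    config = config or TrainConfig()
    per_case = []
    for stack, gt in cases:
        pred = predict_case(model, stack, threshold=config.threshold)
        per_case.append(_case_dice(pred, gt))
    return DiceReport.from_per_case(per_case)


def _batchnorm_layers(module) -> list:
    out = []

    def visit(value):
        if isinstance(value, nn.BatchNorm3d):
            out.append(value)
        elif isinstance(value, nn.Module):
            for child in vars(value).values():
                visit(child)
        elif isinstance(value, (list, tuple)):
            for item in value:
                visit(item)

    visit(module)
    return out


def recalibrate_batchnorm(
    model: Znet, dataset: Sequence[Tuple[ModalityStack, MaskStack]]
) -> None:
    """Replace batch-norm running statistics with the exact mean over the
    dataset's batch statistics.

    With batch size 1 the exponential running averages lag behind the
    weights whenever training is short or the learning rate is large;
    one cheap forward sweep after training removes that train/eval gap.
    """
    bns = _batchnorm_layers(model)
    saved_momentum = [bn.momentum for bn in bns]
    for i, (stack, _) in enumerate(dataset):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)  # cumulative average
        model.forward(stack.data[None].astype(np.float32), train=True)
    for bn, m in zip(bns, saved_momentum):
        bn.momentum = m


def train_model(
    model: Znet,
    dataset: Sequence[Tuple[ModalityStack, MaskStack]],
    config: TrainConfig,
    val_dataset: Optional[Sequence[Tuple[ModalityStack, MaskStack]]] = None,
) -> Tuple[Znet, TrainingHistory]:
    """Run ADAM + binary cross-entropy; deterministic given ``config.seed``.

    The per-epoch sample order is a seeded shuffle.  When a validation
    set is supplied, per-epoch mean region dice is recorded and the best
    epoch's weights are restored at the end.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    first_masks = dataset[0][1]
    if first_masks.data.shape[0] != model.config.out_channels:
        raise ValueError(
            f"model emits {model.config.out_channels} channels but masks have "
            f"{first_masks.data.shape[0]}"
        )
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(list(model.parameters()), lr=config.learning_rate)
    history = TrainingHistory()
    best_dice = -1.0
    best_state = None

    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for idx in order:
            stack, masks = dataset[idx]
            x = stack.data[None].astype(np.float32)
            t = masks.data[None].astype(np.float32)
            probs = model.forward(x, train=True)
            loss = bce_loss(probs, t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, case "
                    f"{stack.case_id}; aborting"
                )
            losses.append(loss)
            optimizer.zero_grad()
            # fused sigmoid + BCE gradient w.r.t. the logits
            glogits = ((probs - t) / t.size).astype(np.float32)
            model.backward(glogits)
            optimizer.step()
        mean_loss = float(np.mean(losses))
        history.train_loss.append(mean_loss)

        if val_dataset:
            recalibrate_batchnorm(model, dataset)
            report = evaluate_dataset(model, val_dataset, config)
            history.val_dice.append(dict(report.region_means))
            mean_dice = report.overall_mean
            if mean_dice > best_dice:
                best_dice = mean_dice
                best_state = (
                    [p.data.copy() for p in model.parameters()],
                    [(bn.running_mean.copy(), bn.running_var.copy())
                     for bn in _batchnorm_layers(model)],
                )
                history.best_epoch = epoch
            log.info(
                "epoch %d: loss=%.5f val_dice=%s", epoch, mean_loss,
                {k: round(v, 4) for k, v in report.region_means.items()},
            )
        else:
            log.info("epoch %d: loss=%.5f", epoch, mean_loss)

    if best_state is not None:
        params, stats = best_state
        for p, saved in zip(model.parameters(), params):
            p.data[...] = saved
        for bn, (mean, var) in zip(_batchnorm_layers(model), stats):
            bn.running_mean[...] = mean
            bn.running_var[...] = var
    else:
        recalibrate_batchnorm(model, dataset)
    return model, history


def split_dataset(
    dataset: Sequence, train_fraction: float, seed: int
) -> Tuple[list, list]:
    """Seeded random train/validation split (no stratification)."""
    idx = np.random.default_rng(seed).permutation(len(dataset))
    n_train = max(1, int(round(train_fraction * len(dataset))))
    n_train = min(n_train, len(dataset) - 1) if len(dataset) > 1 else 1
    train = [dataset[i] for i in idx[:n_train]]
    val = [dataset[i] for i in idx[n_train:]]
    return train, val


def export_overlay(
    stack: ModalityStack,
    gt: MaskStack,
    pred: MaskStack,
    slice_index: int,
    path,
) -> None:
    """Write a 3-panel PNG of one axial slice: ground truth overlay,
    prediction overlay, and their overlap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depth = stack.data.shape[3]
    if not (0 <= slice_index < depth):
        raise IndexError(f"slice index {slice_index} out of range [0, {depth})")

    # axial slice = fixed index along the last (slice-stacking) axis
    img = stack.data[0, :, :, slice_index]
    gt_wt = gt.data[0, :, :, slice_index].astype(bool)
    pred_wt = pred.data[0, :, :, slice_index].astype(bool)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    titles = ("ground truth", "prediction", "overlap")
    overlays = (
        [(gt_wt, (0.0, 0.9, 0.2))],
        [(pred_wt, (0.9, 0.2, 0.2))],
        [(gt_wt & ~pred_wt, (0.0, 0.9, 0.2)),
         (pred_wt & ~gt_wt, (0.9, 0.2, 0.2)),
         (gt_wt & pred_wt, (0.95, 0.85, 0.1))],
    )
    for ax, title, layers in zip(axes, titles, overlays):
        ax.imshow(img.T, cmap="gray", origin="lower")
        for mask, color in layers:
            rgba = np.zeros(mask.shape + (4,), dtype=np.float32)
            rgba[mask] = (*color, 0.5)
            ax.imshow(np.transpose(rgba, (1, 0, 2)), origin="lower")
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
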
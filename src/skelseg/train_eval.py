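"""Training harness, confusion counting, IoU/Dice metrics and the
(F, E, training-order) experiment grid.

Segmentation quality is assessed pixel-wise against the ground truth over
the whole test volume (global aggregation, not per-slice averaging):

    IoU(mask)  = TP / (TP + FP + FN)        Dice(mask) = 2TP / (2TP + FP + FN)
    IoU(bg)    = TN / (TN + FP + FN)        Dice(bg)   = 2TN / (2TN + FP + FN)
    IoU        = mean of the two            Dice       = mean of the two

A trained model whose test prediction is uniformly background has failed to
converge to a segmentation and is flagged rather than scored as best.  The
best grid cell is chosen by Dice, ties broken by Dice(mask), then TP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dataset import SliceDataset, SplitRole, TrainingOrder
from .unet import Adam, UNet2D, UNetSpec, binarize_prediction, build_unet
from .volume_io import MaskVolume

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "ExperimentGrid",
    "GridResult",
    "confusion_counts",
    "iou_metrics",
    "dice_metrics",
    "compute_metrics",
    "is_convergent",
    "train_model",
    "predict_dataset",
    "run_grid",
    "select_best",
]

logger = logging.getLogger(__name__)

DEFAULT_LR = 3e-3
DEFAULT_BATCH_SIZE = 4


class ConfusionCounts(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int


class IoUMetrics(NamedTuple):
    iou_mask: float
    iou_background: float
    iou_mean: float


class DiceMetrics(NamedTuple):
    dice_mask: float
    dice_background: float
    dice_mean: float


@dataclass(frozen=True)
class SegMetrics:
    """Confusion counts plus the six pixel-wise indices."""

    tp: int
    tn: int
    fp: int
    fn: int
    iou_mask: float
    iou_background: float
    iou_mean: float
    dice_mask: float
    dice_background: float
    dice_mean: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary_array(vol) -> np.ndarray:
    arr = vol.voxels if isinstance(vol, MaskVolume) else np.asarray(vol)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("masks must be binary")
    return arr.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Pixel counts aggregated over the whole volume."""
    p = _as_binary_array(pred)
    t = _as_binary_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float) -> float:
    # Vacuous agreement (empty set on both sides) counts as perfect.
    return num / den if den > 0 else 1.0


def iou_metrics(counts: ConfusionCounts) -> IoUMetrics:
    """Jaccard indices for mask, background, and their mean."""
    tp, tn, fp, fn = counts
    if min(counts) < 0:
        raise ValueError("counts must be non-negative")
    mask = _ratio(tp, tp + fp + fn)
    background = _ratio(tn, tn + fp + fn)
    return IoUMetrics(mask, background, (mask + background) / 2.0)


def dice_metrics(counts: ConfusionCounts) -> DiceMetrics:
    """Dice indices for mask, background, and their mean."""
    tp, tn, fp, fn = counts
    if min(counts) < 0:
        raise ValueError("counts must be non-negative")
    mask = _ratio(2 * tp, 2 * tp + fp + fn)
    background = _ratio(2 * tn, 2 * tn + fp + fn)
    return DiceMetrics(mask, background, (mask + background) / 2.0)


def compute_metrics(pred, truth) -> SegMetrics:
    counts = confusion_counts(pred, truth)
    return SegMetrics(*counts, *iou_metrics(counts), *dice_metrics(counts))


def is_convergent(pred) -> bool:
    """False iff the prediction classifies every pixel as background."""
    return bool(np.any(_as_binary_array(pred)))


# ---------------------------------------------------------------------------
# training


def _input_to_unit(stack: np.ndarray) -> np.ndarray:
    # normalized [0, 255] gray levels -> [0, 1] at the model boundary
    return np.asarray(stack, dtype=np.float64) / 255.0


def train_model(
    spec: UNetSpec,
    dataset: SliceDataset,
    order: TrainingOrder,
    epochs: int,
    seed: int = 0,
    lr: float = DEFAULT_LR,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> tuple[UNet2D, list[dict]]:
    """Fit a U-Net for ``epochs`` epochs, visiting the sets in the given order.

    Within each epoch the dataset's sets are presented in ``order``; batches
    run through each set in its stored sequence.  The history records the
    mean pixel-wise BCE loss per (epoch, set).  With ``epochs=0`` the
    freshly initialized model is returned with an empty history.
    """
    if dataset.split_role is not SplitRole.TRAIN:
        raise ValueError("train_model requires a training dataset")
    if not dataset.sets or any(s[0].shape[0] == 0 for s in dataset.sets):
        raise ValueError("empty dataset")
    if len(order.order) != len(dataset.sets):
        raise ValueError("training order length does not match the number of sets")
    model = build_unet(spec, seed=seed)
    optimizer = Adam(model, lr=lr)
    history: list[dict] = []
    for epoch in range(epochs):
        for set_index in order.zero_based():
            inputs, outputs = dataset.sets[set_index]
            x = _input_to_unit(inputs)
            y = np.asarray(outputs, dtype=np.float64)
            losses = []
            for start in range(0, x.shape[0], batch_size):
                loss = model.train_step_grads(
                    x[start : start + batch_size], y[start : start + batch_size]
                )
                optimizer.step()
                losses.append(loss)
            history.append(
                {"epoch": epoch, "set_index": set_index + 1, "loss": float(np.mean(losses))}
            )
    return model, history


def predict_dataset(
    model: UNet2D, dataset: SliceDataset, cut: float = 0.5, batch_size: int = 16
) -> np.ndarray:
    """Slice-wise inference over every set of a dataset; stacked binary masks."""
    preds = []
    for inputs, _ in dataset.sets:
        x = _input_to_unit(inputs)
        for start in range(0, x.shape[0], batch_size):
            prob = model.forward(x[start : start + batch_size])
            preds.append(binarize_prediction(prob, cut))
    return np.concatenate(preds, axis=0)


# ---------------------------------------------------------------------------
# the experiment grid


@dataclass
class ExperimentGrid:
    """The (F, E, training order) grid of one normalization experiment."""

    f_values: tuple[int, ...] = (2, 4, 8)
    e_values: tuple[int, ...] = (5, 10, 20)
    orders: tuple[TrainingOrder, ...] = ()
    experiment: str = "A"
    input_size: tuple[int, int] = (64, 64)

    @property
    def size(self) -> int:
        return len(self.f_values) * len(self.e_values) * len(self.orders)


@dataclass
class GridResult:
    """Per-cell metrics (or non-convergence flags) and the selected best cell."""

    rows: list[dict]
    best: dict | None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def select_best(rows: list[dict]) -> dict | None:
    """Best convergent cell by Dice, then Dice(mask), then TP."""
    convergent = [r for r in rows if r.get("convergent")]
    if not convergent:
        return None
    return max(convergent, key=lambda r: (r["dice_mean"], r["dice_mask"], r["tp"]))


def run_grid(
    grid: ExperimentGrid,
    train: SliceDataset,
    test: SliceDataset,
    seed: int = 0,
    lr: float = DEFAULT_LR,
    batch_size: int = DEFAULT_BATCH_SIZE,
    cut: float = 0.5,
) -> GridResult:
    """Train and evaluate every (F, E, order) cell on the test set.

    Each cell gets a deterministic seed derived from ``seed`` and its index,
    so cells are independently reproducible.  Non-convergent cells (all-
    background prediction) are flagged and excluded from best-cell selection.
    """
    if not grid.orders:
        raise ValueError("grid has no training orders")
    truth = np.concatenate([out for _, out in test.sets], axis=0)
    rows: list[dict] = []
    cell = 0
    for f in grid.f_values:
        for e in grid.e_values:
            for order in grid.orders:
                cell_seed = (seed * 1000003 + cell) % 2**31
                cell += 1
                spec = UNetSpec(f_channels=f, input_size=grid.input_size)
                model, history = train_model(
                    spec, train, order, epochs=e, seed=cell_seed,
                    lr=lr, batch_size=batch_size,
                )
                pred = predict_dataset(model, test, cut=cut)
                convergent = is_convergent(pred)
                metrics = compute_metrics(pred, truth)
                rows.append(
                    {
                        "experiment": grid.experiment,
                        "F": f,
                        "E": e,
                        "order_id": order.order_id,
                        "order": order.order,
                        "seed": cell_seed,
                        "convergent": convergent,
                        "final_loss": history[-1]["loss"] if history else float("nan"),
                        **{k: getattr(metrics, k) for k in (
                            "tp", "tn", "fp", "fn",
                            "iou_mask", "iou_background", "iou_mean",
                            "dice_mask", "dice_background", "dice_mean",
                        )},
                    }
                )
    best = select_best(rows)
    if best is None:
        logger.warning("all %d grid cells were non-convergent", len(rows))
    return GridResult(rows=rows, best=best)
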
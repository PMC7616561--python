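"""Experimental protocol: splits, training, thresholded-IoU evaluation, reports.

The training objective is mean voxel-wise binary cross-entropy optimized
with Adam; reconstruction accuracy is the thresholded intersection-over-
union (IoU) of the predicted occupancy binarized at each threshold against
the binary ground truth, with the "peak IoU" the maximum over thresholds.
Comparison tables between a baseline and a variant network are reported as
per-cell percentage differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epivox import ReconstructionModel
from .nn import Adam, binary_cross_entropy
from .viewslice import VoxelGrid

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "IoUResult",
    "EvalReport",
    "split_dataset",
    "threshold_iou",
    "train",
    "evaluate",
    "mean_volume_baseline",
    "pct_diff_report",
]

DEFAULT_THRESHOLDS = (0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def validate(self) -> None:
        if len(self.ratios) != 3 or not all(0 < r < 1 for r in self.ratios):
            raise ValueError("ratios must be three fractions in (0, 1)")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 8
    iou_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("adam_beta1", "adam_beta2"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        t = self.iou_thresholds
        if not all(0 < x < 1 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("iou_thresholds must be strictly increasing in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class IoUResult:
    threshold: float
    intersection_count: int
    union_count: int

    @property
    def iou(self) -> float:
        # both empty -> perfect agreement
        return 1.0 if self.union_count == 0 else self.intersection_count / self.union_count


def split_dataset(ids: list, spec: SplitSpec) -> tuple[list, list, list]:
    """Disjoint, exhaustive train/val/test split, reproducible from the seed.

    Ids are shuffled by the seed; sizes are floor(n*train), floor(n*val),
    and the remainder goes to test.
    """
    spec.validate()
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = int(np.floor(n * spec.ratios[0]))
    n_val = int(np.floor(n * spec.ratios[1]))
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def _values(grid) -> np.ndarray:
    return grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid)


def threshold_iou(pred, gt, t: float) -> IoUResult:
    """IoU of the prediction binarized at ``value > t`` against binary gt."""
    p = _values(pred)
    g = _values(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    pb = p > t
    gb = g > 0.5
    inter = int(np.count_nonzero(pb & gb))
    union = int(np.count_nonzero(pb | gb))
    return IoUResult(threshold=t, intersection_count=inter, union_count=union)


@dataclass
class EvalReport:
    thresholds: tuple[float, ...]
    per_sample: np.ndarray  # (S, T) IoUs
    mean_per_threshold: np.ndarray  # (T,)
    peak_iou: float  # max over thresholds of the mean

    def as_table(self) -> dict[float, float]:
        return {t: float(m) for t, m in zip(self.thresholds, self.mean_per_threshold)}


def _predict(model, views: np.ndarray) -> np.ndarray:
    from .nn import Tensor

    out = model(views[None]) if views.ndim == 3 else model(views)
    data = out.data if isinstance(out, Tensor) else np.asarray(out)
    return data[0] if data.ndim == 4 else data


def evaluate(model, dataset, thresholds=DEFAULT_THRESHOLDS) -> EvalReport:
    """Mean thresholded IoU over a dataset of (views, ground-truth) pairs."""
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must be non-empty")
    rows = []
    for views, gt in dataset:
        pred = _predict(model, np.asarray(views))
        rows.append([threshold_iou(pred, gt, t).iou for t in thresholds])
    per_sample = np.asarray(rows)
    mean = per_sample.mean(axis=0)
    return EvalReport(
        thresholds=tuple(thresholds),
        per_sample=per_sample,
        mean_per_threshold=mean,
        peak_iou=float(mean.max()),
    )


class MeanVolumePredictor:
    """Baseline that always predicts the mean of the training ground truths."""

    def __init__(self, gts: list[np.ndarray]):
        self.volume = np.mean([_values(g).astype(np.float64) for g in gts], axis=0)

    def __call__(self, views) -> np.ndarray:
        b = 1 if np.asarray(views).ndim == 3 else len(views)
        return np.repeat(self.volume[None], b, axis=0)


def mean_volume_baseline(train_set) -> MeanVolumePredictor:
    return MeanVolumePredictor([gt for _, gt in train_set])


def train(
    model: ReconstructionModel,
    dataset,
    cfg: TrainConfig,
    val_set=None,
) -> dict[str, list]:
    """Optimize mean voxel-wise BCE with Adam; returns per-epoch history.

    Deterministic given the config seed (which drives batch shuffling) and
    the model's initialization seed.  History keys: ``loss`` (mean training
    BCE per epoch) and, when ``val_set`` is given, ``val_peak_iou``.
    """
    cfg.validate()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must be non-empty")
    for views, _ in dataset:
        v = np.asarray(views).shape[0]
        if v > model.spec.max_views:
            raise ValueError(f"sample has {v} views, model capacity {model.spec.max_views}")
    opt = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    rng = np.random.default_rng(cfg.seed)
    history: dict[str, list] = {"loss": []}
    if val_set is not None:
        history["val_peak_iou"] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [dataset[i] for i in order[lo : lo + cfg.batch_size]]
            views = np.stack([np.asarray(v) for v, _ in batch])
            gts = np.stack([_values(g) for _, g in batch]).astype(np.float64)
            opt.zero_grad()
            pred = model(views)
            loss = binary_cross_entropy(pred, gts)
            loss.backward()
            opt.step()
            losses.append(loss.data.item())
        history["loss"].append(float(np.mean(losses)))
        if val_set is not None:
            history["val_peak_iou"].append(evaluate(model, val_set, cfg.iou_thresholds).peak_iou)
    return history


def pct_diff_report(baseline_ious, variant_ious, decimals: int | None = None):
    """Per-cell percentage difference 100*(variant - baseline)/baseline.

    Cells with a zero baseline are undefined: the value is NaN and the
    returned mask flags them.  ``decimals`` optionally rounds to the
    precision of a printed table.
    """
    b = np.asarray(baseline_ious, dtype=np.float64)
    v = np.asarray(variant_ious, dtype=np.float64)
    if b.shape != v.shape:
        raise ValueError(f"shape mismatch: {b.shape} vs {v.shape}")
    undefined = b == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (v - b) / b
    pct = np.where(undefined, np.nan, pct)
    if decimals is not None:
        pct = np.round(pct, decimals)
    return pct, undefined
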
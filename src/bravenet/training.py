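"""Training protocol and the cross-validation experiment.

Networks are optimized with Adam on the (optionally deep-supervised)
soft-Dice composite loss, with Glorot-uniform initial weights, patch-level
validation-loss monitoring and early stopping (patience 3, best-epoch
weight restore).  `run_cross_validation` orchestrates the 4-fold
experiment: stratified splits, vessel-centric patch sampling on training
volumes, training, whole-volume reconstruction of every test volume and
five-metric evaluation, aggregated as mean (SD) across folds.

A statsmodels-style facade is provided: build a
:class:`VesselSegmentationModel` from volumes + labels, call ``fit()``,
and receive a :class:`CrossValidationResults` carrying per-fold metrics,
trained fold networks, histories and a ``summary()`` table.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import losses
from .architectures import ArchitectureConfig, Network, build_network
from .autodiff import Adam, Tensor
from .evaluation import METRIC_COLUMNS, EvaluationReport, evaluate_segmentation
from .inference import binarize, predict_volume
from .sampling import (
    compute_heuristic_mask,
    extract_patch,
    make_cv_splits,
    sample_patch_centers,
)
from .volume_io import BinaryLabelVolume, Volume

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "EarlyStopper",
    "PatchDataset",
    "train_model",
    "select_learning_rate",
    "aggregate_fold_metrics",
    "run_cross_validation",
    "CrossValidationResults",
    "VesselSegmentationModel",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    lr_candidates: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 3
    seed: int = 0
    loss_eps: float = 1.0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": range(len(self.train_loss)),
             "train_loss": self.train_loss, "val_loss": self.val_loss}
        )


class EarlyStopper:
    """Stop when validation loss fails to improve for `patience`
    consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.since_best = 0
        else:
            self.since_best += 1
        return self.since_best >= self.patience


class PatchDataset:
    """Sampled patch centers over a set of volumes; batches of co-centred
    primary/context/label patches are materialized on demand.

    Centers are drawn once per volume (2,000 per volume, 50%
    vessel-centric by default) within the heuristic air-exclusion mask.
    """

    def __init__(self, pairs, primary_patch=(64, 64, 8), n_centers=2000,
                 vessel_fraction=0.5, seed=0, with_context=True):
        self.pairs = list(pairs)
        self.primary_patch = tuple(primary_patch)
        self.context_patch = tuple(2 * s for s in primary_patch)
        self.with_context = with_context
        self.index: list[tuple[int, tuple[int, int, int]]] = []
        for k, (vol, lab) in enumerate(self.pairs):
            mask = compute_heuristic_mask(vol)
            centers = sample_patch_centers(
                lab, mask, n=n_centers, vessel_fraction=vessel_fraction,
                seed=seed + 7919 * k,
            )
            self.index.extend((k, c) for c in centers)

    def __len__(self):
        return len(self.index)

    def batch(self, ids):
        primary, context, label = [], [], []
        for i in ids:
            k, c = self.index[i]
            vol, lab = self.pairs[k]
            primary.append(extract_patch(vol, c, self.primary_patch, 0))
            label.append(extract_patch(lab, c, self.primary_patch, 0))
            if self.with_context:
                context.append(extract_patch(vol, c, self.context_patch, 0))
        p = np.stack(primary).astype(np.float32)[:, None]
        g = np.stack(label).astype(np.float32)[:, None]
        ctx = (np.stack(context).astype(np.float32)[:, None]
               if self.with_context else None)
        return p, ctx, g


def _batches(n, batch_size, order=None):
    idx = np.arange(n) if order is None else np.asarray(order)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def _epoch_loss(net: Network, data: PatchDataset, weights, cfg,
                train: bool = False):
    """Mean composite loss over a dataset in evaluation mode."""
    total, count = 0.0, 0
    for ids in _batches(len(data), cfg.batch_size):
        p, ctx, g = data.batch(ids)
        heads = net.forward(
            Tensor(p), Tensor(ctx) if ctx is not None else None, train=train
        )
        loss = losses.composite_loss_tensor(heads, g, weights, cfg.loss_eps)
        total += loss.item() * len(ids)
        count += len(ids)
    return total / max(count, 1)


def train_model(net: Network, train_data: PatchDataset,
                val_data: PatchDataset, cfg: TrainingConfig
                ) -> tuple[Network, TrainingHistory]:
    """Adam optimization of the composite soft-Dice loss with early
    stopping on patch-level validation loss; the returned network carries
    the best-validation-epoch weights.  Fully reproducible under
    ``cfg.seed``."""
    if len(train_data) == 0:
        raise ValueError("empty training stream")
    if len(val_data) == 0:
        raise ValueError(
            "empty validation stream: early stopping needs validation data"
        )
    n_heads = 3 if net.cfg.has_deep_supervision else 1
    weights = losses.ds_weights(n_heads)
    optimizer = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    net.reseed_dropout(cfg.seed + 1)
    stopper = EarlyStopper(cfg.patience)
    history = TrainingHistory()
    best_state = None

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_data))
        epoch_total, n_seen = 0.0, 0
        for ids in _batches(len(train_data), cfg.batch_size, order):
            p, ctx, g = train_data.batch(ids)
            heads = net.forward(
                Tensor(p), Tensor(ctx) if ctx is not None else None,
                train=True,
            )
            loss = losses.composite_loss_tensor(heads, g, weights,
                                                cfg.loss_eps)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_total += loss.item() * len(ids)
            n_seen += len(ids)
        history.train_loss.append(epoch_total / n_seen)

        val_loss = _epoch_loss(net, val_data, weights, cfg, train=False)
        history.val_loss.append(val_loss)

        if val_loss < stopper.best:
            best_state = (
                {k: v.data.copy() for k, v in net.params.items()},
                copy.deepcopy(net.bn_states),
            )
        if stopper.update(epoch, val_loss):
            history.stopped_early = True
            break

    history.best_epoch = stopper.best_epoch
    if best_state is not None:
        params, bn_states = best_state
        for k, v in params.items():
            net.params[k].data = v
        net.bn_states = bn_states
    return net, history


def select_learning_rate(candidates, fold_results) -> float:
    """Candidate with the highest mean whole-volume validation DSC
    across folds; exact ties break toward the smaller rate."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no learning-rate candidates")
    best = None
    for lr in candidates:
        mean = float(np.mean(fold_results[lr]))
        if best is None or mean > best[0] or (mean == best[0] and lr < best[1]):
            best = (mean, lr)
    return best[1]


def aggregate_fold_metrics(fold_metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per metric across folds (ddof=0 population SD is not
    used; SD matches pandas' sample SD over folds)."""
    return pd.DataFrame(
        {"mean": fold_metrics.mean(axis=0), "sd": fold_metrics.std(axis=0)}
    )


class CrossValidationResults:
    """Results of one cross-validated experiment for one variant."""

    def __init__(self, variant, fold_metrics, networks, histories, reports,
                 splits):
        self.variant = variant
        self.fold_metrics = fold_metrics
        self.networks = networks
        self.histories = histories
        self.reports = reports
        self.splits = splits

    @property
    def mean_metrics(self) -> pd.Series:
        return self.fold_metrics.mean(axis=0)

    def table(self) -> pd.DataFrame:
        """One formatted "mean (SD)" row per variant, in the shape of a
        cross-validation results table."""
        agg = aggregate_fold_metrics(self.fold_metrics)
        row = {
            f"{m} (SD)": f"{agg.loc[m, 'mean']:.3f} ({agg.loc[m, 'sd']:.3f})"
            for m in METRIC_COLUMNS
        }
        return pd.DataFrame([row], index=[self.variant])

    def predict(self, volume: Volume, threshold: float = 0.5
                ) -> BinaryLabelVolume:
        """Ensemble prediction of the fold networks on a raw volume."""
        from .inference import ensemble_predict

        return ensemble_predict(self.networks, volume, threshold)

    def summary(self) -> str:
        agg = aggregate_fold_metrics(self.fold_metrics)
        lines = [
            f"Cross-validation results — variant: {self.variant}",
            f"folds: {len(self.fold_metrics)}",
            "-" * 44,
            f"{'metric':<12}{'mean':>12}{'SD':>12}",
        ]
        for m in METRIC_COLUMNS:
            lines.append(
                f"{m:<12}{agg.loc[m, 'mean']:>12.4f}{agg.loc[m, 'sd']:>12.4f}"
            )
        return "\n".join(lines)


def run_cross_validation(dataset, arch: ArchitectureConfig,
                         cfg: TrainingConfig, folds: int = 4,
                         val_fraction: float = 0.15, n_centers: int = 2000,
                         vessel_fraction: float = 0.5, stride=None,
                         threshold: float = 0.5) -> CrossValidationResults:
    """Run the full cross-validated experiment on (volume, labels, source)
    triples: per fold, sample patches from training volumes, train,
    reconstruct every test volume whole, and evaluate all five metrics."""
    sources: dict[str, int] = {}
    id_to_item: dict[str, tuple[Volume, BinaryLabelVolume]] = {}
    for vol, lab, source in dataset:
        i = sources.get(source, 0)
        id_to_item[f"{source}_{i:04d}"] = (vol, lab)
        sources[source] = i + 1
    splits = make_cv_splits(sources, folds=folds, val_fraction=val_fraction,
                            seed=cfg.seed)

    rows, networks, histories, reports = [], [], [], {}
    for split in splits:
        train_pairs = [id_to_item[i] for i in split.train_ids]
        val_pairs = [id_to_item[i] for i in split.val_ids]
        train_data = PatchDataset(
            train_pairs, primary_patch=arch.primary_patch,
            n_centers=n_centers, vessel_fraction=vessel_fraction,
            seed=cfg.seed + 17 * split.fold_index,
            with_context=arch.has_context,
        )
        val_data = PatchDataset(
            val_pairs, primary_patch=arch.primary_patch,
            n_centers=n_centers, vessel_fraction=vessel_fraction,
            seed=cfg.seed + 17 * split.fold_index + 7,
            with_context=arch.has_context,
        )
        net = build_network(arch, seed=cfg.seed + 100 + split.fold_index)
        net, history = train_model(net, train_data, val_data, cfg)
        networks.append(net)
        histories.append(history)

        fold_reports = []
        for test_id in split.test_ids:
            vol, lab = id_to_item[test_id]
            prob = predict_volume(net, vol, stride=stride)
            rep = evaluate_segmentation(binarize(prob, threshold), lab)
            reports[test_id] = rep
            fold_reports.append(rep.as_dict())
        rows.append(pd.DataFrame(fold_reports).mean(axis=0))

    fold_metrics = pd.DataFrame(rows)[list(METRIC_COLUMNS)]
    fold_metrics.index.name = "fold"
    return CrossValidationResults(arch.variant, fold_metrics, networks,
                                  histories, reports, splits)


class VesselSegmentationModel:
    """Model-object facade over the cross-validated training pipeline.

    Parameters
    ----------
    dataset : list of (Volume, BinaryLabelVolume, source-tag) triples
    arch : ArchitectureConfig
    training : TrainingConfig
    """

    def __init__(self, dataset, arch: ArchitectureConfig | None = None,
                 training: TrainingConfig | None = None, folds: int = 4,
                 val_fraction: float = 0.15, n_centers: int = 2000,
                 vessel_fraction: float = 0.5):
        self.dataset = list(dataset)
        self.arch = arch or ArchitectureConfig()
        self.training = training or TrainingConfig()
        self.folds = folds
        self.val_fraction = val_fraction
        self.n_centers = n_centers
        self.vessel_fraction = vessel_fraction

    @classmethod
    def from_volumes(cls, volumes, labels, sources=None, **kwargs):
        if sources is None:
            sources = ["default"] * len(volumes)
        return cls(list(zip(volumes, labels, sources)), **kwargs)

    def fit(self, seed: int | None = None) -> CrossValidationResults:
        cfg = self.training
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
        return run_cross_validation(
            self.dataset, self.arch, cfg, folds=self.folds,
            val_fraction=self.val_fraction, n_centers=self.n_centers,
            vessel_fraction=self.vessel_fraction,
        )
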
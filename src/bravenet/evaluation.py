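"""Segmentation evaluation: Precision, Recall, DSC, AVD and 95HD.

Overlap metrics come from the voxel-wise confusion table.  Distance
metrics are computed over ALL foreground voxels (not extracted surfaces):
for each foreground voxel of one volume the Euclidean distance to the
nearest foreground voxel of the other is taken (efficiently via a
distance transform), then

* AVD  = max of the two directed mean nearest-neighbour distances,
* 95HD = max of the two directed 95th-percentile distances
  (linear interpolation between order statistics).

Distances are reported in voxel units by default; pass a physical
``spacing`` for millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BinaryLabelVolume

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_counts",
    "overlap_metrics",
    "directed_avg_distance",
    "avd",
    "hd95",
    "evaluate_segmentation",
]

METRIC_COLUMNS = ("DSC", "AVD", "95HD", "Precision", "Recall")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationReport:
    """Five metrics plus confusion counts for one (pred, gt) pair."""

    dsc: float
    precision: float
    recall: float
    avd: float
    hd95: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {
            "DSC": self.dsc,
            "AVD": self.avd,
            "95HD": self.hd95,
            "Precision": self.precision,
            "Recall": self.recall,
        }


def _as_bool(v) -> np.ndarray:
    data = v.data if isinstance(v, BinaryLabelVolume) else np.asarray(v)
    return data.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Voxel-wise 2x2 confusion table between two binary volumes."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(DSC, precision, recall) from confusion counts.

    Empty-denominator conventions: DSC is 1 when both foregrounds are
    empty; precision is 1 for an empty prediction only if the ground
    truth is also empty (else 0); recall is vacuously 1 when the ground
    truth is empty.
    """
    if 2 * c.tp + c.fp + c.fn == 0:
        dsc = 1.0
    else:
        dsc = 2.0 * c.tp / (2 * c.tp + c.fp + c.fn)
    if c.tp + c.fp == 0:
        precision = 1.0 if c.fn == 0 else 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall = 1.0  # vacuously complete: nothing to recall
    else:
        recall = c.tp / (c.tp + c.fn)
    return dsc, precision, recall


def directed_avg_distance(A, B, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean over voxels of A of the Euclidean distance to the nearest
    voxel of B.  A and B are boolean grids (or coordinate arrays matched
    to a grid elsewhere); +inf if B is empty."""
    d = _directed_distances(_as_bool(A), _as_bool(B), spacing)
    if d is None:
        return float("inf")
    return float(d.mean())


def _directed_distances(a, b, spacing):
    """Nearest-B distance for every foreground voxel of a; None if b
    empty, empty array if a empty."""
    if not b.any():
        if a.any():
            warnings.warn("empty reference foreground: distance is +inf")
            return None
        return np.zeros(0)
    dt = ndimage.distance_transform_edt(~b, sampling=spacing)
    return dt[a]


def _distance_pair(pred, gt, spacing):
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not p.any() and not g.any():
        warnings.warn("both foregrounds empty: distance metrics are 0")
        return None
    if p.any() != g.any():
        warnings.warn("one foreground empty: distance metrics are +inf")
        return np.array([np.inf]), np.array([np.inf])
    return (
        _directed_distances(p, g, spacing),
        _directed_distances(g, p, spacing),
    )


def avd(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average Hausdorff distance: max of the two directed means."""
    pair = _distance_pair(pred, gt, spacing)
    if pair is None:
        return 0.0
    d_pg, d_gp = pair
    return float(max(d_pg.mean(), d_gp.mean()))


def hd95(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile Hausdorff distance: max of the two directed
    95th-percentile nearest-neighbour distance distributions."""
    pair = _distance_pair(pred, gt, spacing)
    if pair is None:
        return 0.0
    d_pg, d_gp = pair
    if np.isinf(d_pg).any() or np.isinf(d_gp).any():
        return float("inf")
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


def evaluate_segmentation(pred, gt, spacing=(1.0, 1.0, 1.0)
                          ) -> EvaluationReport:
    """Full five-metric report for one (prediction, ground truth) pair."""
    c = confusion_counts(pred, gt)
    dsc, precision, recall = overlap_metrics(c)
    return EvaluationReport(
        dsc=dsc,
        precision=precision,
        recall=recall,
        avd=avd(pred, gt, spacing),
        hd95=hd95(pred, gt, spacing),
        counts=c,
    )
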
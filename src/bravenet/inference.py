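"""Whole-volume inference: tile the volume into patches, run the network,
reconstruct the probability map, binarize, and ensemble fold models.

Prediction deliberately takes a raw intensity volume — no mask and no
normalization step are applied; the networks' initial batch-normalization
layer absorbs intensity scaling.
"""

from __future__ import annotations

import numpy as np

from .volume_io import BinaryLabelVolume, ProbabilityVolume, Volume

__all__ = [
    "tile_centers",
    "predict_volume",
    "binarize",
    "ensemble_probability",
    "ensemble_predict",
]


def _axis_starts(dim: int, patch: int, stride: int) -> list[int]:
    if dim <= patch:
        return [0]
    starts = list(range(0, dim - patch + 1, stride))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)  # clamp the last tile to the boundary
    return starts


def tile_centers(shape, patch, stride) -> list[tuple[int, int, int]]:
    """Patch centers covering every voxel of `shape`; the last tile per
    axis is clamped to the boundary."""
    patch = tuple(int(p) for p in patch)
    stride = tuple(int(s) for s in stride)
    if any(s < 1 for s in stride):
        raise ValueError("stride components must be >= 1")
    if any(p > s for p, s in zip(patch, shape)):
        raise ValueError(f"patch {patch} larger than volume {tuple(shape)}")
    axes = [
        [st + p // 2 for st in _axis_starts(d, p, s)]
        for d, p, s in zip(shape, patch, stride)
    ]
    return [(x, y, z) for x in axes[0] for y in axes[1] for z in axes[2]]


def predict_volume(net, v: Volume, stride=None,
                   batch_size: int = 4) -> ProbabilityVolume:
    """Reconstruct the whole-volume probability map from patch-wise
    predictions of the FINAL head; overlapping voxels are averaged.

    `net` needs a ``cfg`` with ``primary_patch`` / ``has_context`` and a
    ``predict_patches(primary, context)`` method.
    """
    from .sampling import extract_patch

    patch = tuple(net.cfg.primary_patch)
    if stride is None:
        stride = patch
    centers = tile_centers(v.shape, patch, stride)
    context_patch = tuple(2 * p for p in patch)

    accum = np.zeros(v.shape, dtype=np.float64)
    count = np.zeros(v.shape, dtype=np.int32)
    for i in range(0, len(centers), batch_size):
        chunk = centers[i:i + batch_size]
        primary = np.stack(
            [extract_patch(v, c, patch, pad_value=0) for c in chunk]
        )
        context = None
        if net.cfg.has_context:
            context = np.stack(
                [extract_patch(v, c, context_patch, pad_value=0)
                 for c in chunk]
            )
        probs = net.predict_patches(primary, context)
        for c, prob in zip(chunk, probs):
            sl_dst, sl_src = [], []
            for ci, p, dim in zip(c, patch, v.shape):
                start = ci - p // 2
                lo, hi = max(start, 0), min(start + p, dim)
                sl_dst.append(slice(lo, hi))
                sl_src.append(slice(lo - start, hi - start))
            accum[tuple(sl_dst)] += prob[tuple(sl_src)]
            count[tuple(sl_dst)] += 1
    out = accum / np.maximum(count, 1)
    return ProbabilityVolume(np.clip(out, 0.0, 1.0).astype(np.float32),
                             v.voxel_size)


def binarize(p: ProbabilityVolume, threshold: float = 0.5
             ) -> BinaryLabelVolume:
    """Label a voxel 1 iff its probability strictly exceeds `threshold`
    (ties at the threshold map to background)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return BinaryLabelVolume((p.data > threshold).astype(np.uint8),
                             p.voxel_size)


def ensemble_probability(nets, v: Volume, stride=None) -> ProbabilityVolume:
    """Voxel-wise arithmetic mean of per-network probability volumes."""
    if not nets:
        raise ValueError("at least one network is required")
    acc = None
    for net in nets:
        p = predict_volume(net, v, stride=stride)
        acc = p.data.astype(np.float64) if acc is None else acc + p.data
    return ProbabilityVolume((acc / len(nets)).astype(np.float32),
                             v.voxel_size)


def ensemble_predict(nets, v: Volume, threshold: float = 0.5,
                     stride=None) -> BinaryLabelVolume:
    """Ensemble by averaging probability maps, then threshold at 0.5."""
    return binarize(ensemble_probability(nets, v, stride=stride), threshold)
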
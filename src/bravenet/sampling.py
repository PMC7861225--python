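"""Training-time sampling machinery.

Covers the heuristic air-exclusion mask (box-mean filter + fixed
intensity threshold), vessel-centric sampling of patch centers, extraction
of co-centred two-scale patches, and the stratified 4-fold
cross-validation splits.  The mask is used only to pre-select training
patches; inference never sees it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryLabelVolume, Volume

__all__ = [
    "PatchSample",
    "FoldSplit",
    "compute_heuristic_mask",
    "sample_patch_centers",
    "centers_to_csv",
    "extract_patch",
    "extract_sample",
    "make_cv_splits",
    "splits_to_json",
    "splits_from_json",
]

PRIMARY_PATCH = (64, 64, 8)
CONTEXT_PATCH = (128, 128, 16)


@dataclass
class PatchSample:
    """Co-centred primary/context intensity patches plus the label patch."""

    center: tuple[int, int, int]
    primary: np.ndarray
    context: np.ndarray
    label: np.ndarray


@dataclass
class FoldSplit:
    """One fold of the stratified cross-validation."""

    fold_index: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    source_of: dict[str, str] = field(default_factory=dict)


def compute_heuristic_mask(v: Volume, window: int = 16,
                           threshold: float = 10.0) -> BinaryLabelVolume:
    """Box-mean the intensities (stride-1 sliding window, replicate edge
    padding) and keep voxels whose local mean strictly exceeds `threshold`.

    Defaults are a 16x16x16 averaging window and a threshold of 10, which
    separate near-zero air from head tissue in raw TOF-like intensities.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if any(window > s for s in v.shape):
        raise ValueError(
            f"window {window} exceeds a volume dimension {v.shape}"
        )
    smoothed = ndimage.uniform_filter(
        v.data.astype(np.float64), size=window, mode="nearest"
    )
    return BinaryLabelVolume((smoothed > threshold).astype(np.uint8),
                             v.voxel_size)


def sample_patch_centers(labels: BinaryLabelVolume, mask: BinaryLabelVolume,
                         n: int = 2000, vessel_fraction: float = 0.5,
                         seed: int = 0) -> list[tuple[int, int, int]]:
    """Sample `n` patch-center voxels inside the mask, with replacement,
    forcing ceil(n * vessel_fraction) of them onto vessel-labelled voxels.

    "Vessel-centric" means the center voxel itself carries label 1.  The
    remaining draws come from non-vessel mask voxels (so the vessel-centric
    quota is exact); with vessel_fraction == 0 they come from the whole
    mask.
    """
    if labels.shape != mask.shape:
        raise ValueError("labels and mask must share a shape")
    if not 0.0 <= vessel_fraction <= 1.0:
        raise ValueError("vessel_fraction must be in [0, 1]")
    if mask.data.sum() == 0:
        raise ValueError("empty mask: no admissible centers")
    rng = np.random.default_rng(seed)
    n_vessel = math.ceil(n * vessel_fraction)
    lab = labels.data.astype(bool)
    msk = mask.data.astype(bool)

    picks = []
    if n_vessel > 0:
        pool = np.argwhere(lab & msk)
        if len(pool) == 0:
            raise ValueError("no vessel voxel inside the mask")
        picks.append(pool[rng.integers(0, len(pool), size=n_vessel)])
    n_bg = n - n_vessel
    if n_bg > 0:
        pool = np.argwhere(msk & ~lab) if vessel_fraction > 0 else np.argwhere(msk)
        if len(pool) == 0:
            pool = np.argwhere(msk)
        picks.append(pool[rng.integers(0, len(pool), size=n_bg)])
    centers = np.concatenate(picks, axis=0)
    rng.shuffle(centers, axis=0)
    return [tuple(int(c) for c in row) for row in centers]


def centers_to_csv(path, volume_id: str, centers,
                   labels: BinaryLabelVolume) -> None:
    """Write sampled centers as CSV rows (id, x, y, z, is_vessel_centric)."""
    with open(path, "w") as fh:
        fh.write("id,x,y,z,is_vessel_centric\n")
        for c in centers:
            fh.write(
                f"{volume_id},{c[0]},{c[1]},{c[2]},{int(labels.data[c])}\n"
            )


def extract_patch(v, center, size, pad_value=0) -> np.ndarray:
    """Extract a patch of exactly `size`, centred on `center` (even sizes
    place the center at index size//2 per axis); out-of-bounds positions
    are filled with `pad_value`."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    shape = data.shape
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= s for c, s in zip(center, shape)):
        raise ValueError(f"center {center} outside volume of shape {shape}")
    size = tuple(int(s) for s in size)
    out = np.full(size, pad_value, dtype=data.dtype)
    src, dst = [], []
    for c, sz, dim in zip(center, size, shape):
        start = c - sz // 2
        lo, hi = max(start, 0), min(start + sz, dim)
        src.append(slice(lo, hi))
        dst.append(slice(lo - start, hi - start))
    out[tuple(dst)] = data[tuple(src)]
    return out


def extract_sample(v: Volume, labels: BinaryLabelVolume, center,
                   primary_size=PRIMARY_PATCH) -> PatchSample:
    """Extract the co-centred primary, context (2x per axis) and label
    patches for one sampled location."""
    context_size = tuple(2 * s for s in primary_size)
    return PatchSample(
        center=tuple(int(c) for c in center),
        primary=extract_patch(v, center, primary_size),
        context=extract_patch(v, center, context_size),
        label=extract_patch(labels, center, primary_size),
    )


def make_cv_splits(cohort_sizes: dict[str, int], folds: int = 4,
                   val_fraction: float = 0.15, seed: int = 0
                   ) -> list[FoldSplit]:
    """Build stratified k-fold train/validation/test splits.

    Per source cohort, each fold's test set receives floor(count/folds)
    ids (remainder ids stay in training across all folds).  From the
    per-fold non-test pool, floor(val_fraction * pool) ids move to
    validation, stratified per source by the same floor rule with any
    shortfall filled from the largest source.  On cohort sizes
    (74, 9, 181) with 4 folds and a 15% carve-out this yields
    170 / 29 / 65 train / validation / test ids in every fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    source_of: dict[str, str] = {}
    test_chunks: dict[str, list[list[str]]] = {}
    remainders: dict[str, list[str]] = {}
    pools: dict[str, list[str]] = {}
    for source in sorted(cohort_sizes):
        count = int(cohort_sizes[source])
        ids = [f"{source}_{i:04d}" for i in range(count)]
        for i in ids:
            source_of[i] = source
        order = list(rng.permutation(len(ids)))
        shuffled = [ids[i] for i in order]
        q = count // folds
        test_chunks[source] = [shuffled[f * q:(f + 1) * q] for f in range(folds)]
        remainders[source] = shuffled[folds * q:]
        pools[source] = shuffled

    splits = []
    for f in range(folds):
        test_ids = []
        pool_by_source: dict[str, list[str]] = {}
        for source in sorted(cohort_sizes):
            test_ids.extend(test_chunks[source][f])
            in_test = set(test_chunks[source][f])
            pool_by_source[source] = [
                i for i in pools[source] if i not in in_test
            ]
        pool_total = sum(len(p) for p in pool_by_source.values())
        target = int(val_fraction * pool_total)
        quotas = {
            s: int(val_fraction * len(p)) for s, p in pool_by_source.items()
        }
        shortfall = target - sum(quotas.values())
        if shortfall > 0:
            largest = max(
                pool_by_source, key=lambda s: (len(pool_by_source[s]), s)
            )
            quotas[largest] += shortfall
        val_ids, train_ids = [], []
        for source in sorted(cohort_sizes):
            pool = pool_by_source[source]
            k = min(quotas[source], len(pool))
            chosen = set(
                pool[i] for i in rng.choice(len(pool), size=k, replace=False)
            ) if k else set()
            val_ids.extend(i for i in pool if i in chosen)
            train_ids.extend(i for i in pool if i not in chosen)
        splits.append(FoldSplit(f, train_ids, val_ids, sorted(test_ids),
                                dict(source_of)))
    return splits


def splits_to_json(splits: list[FoldSplit]) -> str:
    return json.dumps(
        {
            str(s.fold_index): {
                "train": s.train_ids,
                "val": s.val_ids,
                "test": s.test_ids,
                "source_of": s.source_of,
            }
            for s in splits
        },
        indent=1,
    )


def splits_from_json(text: str) -> list[FoldSplit]:
    raw = json.loads(text)
    return [
        FoldSplit(int(k), v["train"], v["val"], v["test"],
                  v.get("source_of", {}))
        for k, v in sorted(raw.items(), key=lambda kv: int(kv[0]))
    ]
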
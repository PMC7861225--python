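"""Synthetic TOF-like vascular phantoms with paired vessel labels.

A phantom emulates the features of a head angiography volume that the
pipeline depends on: near-zero air around a bright ellipsoidal head
(so a box-mean intensity threshold of 10 separates them), a bright
skull-analogue shell, sparse bright tubular vessels (0.3-1.5% of head
voxels, mirroring arterial volume fractions), and bright non-vessel
distractor blobs (sinus/extracranial analogues) that must stay labelled
as background.  All geometry and intensity constants are package
fixtures, not measurements.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import BinaryLabelVolume, Volume, write_volume

__all__ = [
    "PhantomSpec",
    "VesselTree",
    "generate_vessel_tree",
    "rasterize_tree",
    "synthesize_volume",
    "generate_phantom",
    "generate_dataset",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic head volume."""

    shape: tuple[int, int, int] = (128, 128, 32)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.65)
    n_trees: int = 3
    radius_range: tuple[float, float] = (0.6, 1.6)
    branch_prob: float = 0.08
    target_vessel_fraction: float = 0.008
    air_intensity: float = 2.0
    tissue_intensity: float = 80.0
    vessel_intensity: float = 300.0
    skull_intensity: float = 120.0
    distractor_intensity: float = 250.0
    noise_sigma: float = 10.0
    n_distractors: int = 4

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if not 0.003 <= self.target_vessel_fraction <= 0.015:
            raise ValueError(
                "target_vessel_fraction must lie in the physiological "
                "bracket [0.003, 0.015]"
            )
        if self.radius_range[0] < 0.5:
            raise ValueError("minimum tube radius must be >= 0.5 voxel")
        if not (self.vessel_intensity > self.tissue_intensity > 10
                > self.air_intensity):
            raise ValueError(
                "need vessel mean > tissue mean > threshold 10 > air mean"
            )


@dataclass
class VesselTree:
    """Centerline polylines with per-node radii, in voxel coordinates."""

    branches: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def _head_radius(shape):
    # ellipsoid semi-axes; the head fills roughly half the volume so that
    # air/skull border patches exist
    return np.array([0.42 * shape[0], 0.42 * shape[1], 0.44 * shape[2]])


def _normalized_radius(points, shape):
    """Ellipsoidal coordinate: < 1 inside the head, 1 on its surface."""
    center = (np.asarray(shape) - 1) / 2.0
    return np.sqrt(
        (((np.atleast_2d(points) - center) / _head_radius(shape)) ** 2).sum(
            axis=-1
        )
    )


def generate_vessel_tree(spec: PhantomSpec, seed: int) -> VesselTree:
    """Grow one rooted branching tree by a direction-persistent random
    walk inside the head; radii taper monotonically from root to leaf."""
    rng = np.random.default_rng(seed)
    shape = np.asarray(spec.shape, dtype=float)
    center = (shape - 1) / 2.0
    r_min, r_max = spec.radius_range
    step = 1.5
    taper = 0.985

    # root well inside the head
    while True:
        pos = center + (rng.random(3) - 0.5) * _head_radius(spec.shape)
        if _normalized_radius(pos, spec.shape)[0] < 0.5:
            break
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)

    tree = VesselTree()
    queue = [(pos, direction, r_max)]
    # node budget scaled so that n_trees trees together deposit roughly
    # the target vessel fraction of the head volume
    head_voxels = 4.0 / 3.0 * np.pi * np.prod(_head_radius(spec.shape))
    r_mean = 0.5 * (r_min + r_max)
    max_nodes = max(
        8,
        int(spec.target_vessel_fraction * head_voxels
            / (np.pi * r_mean ** 2 * step * max(spec.n_trees, 1))),
    )
    total_nodes = 0
    while queue and total_nodes < max_nodes:
        pos, direction, radius = queue.pop(0)
        points, radii = [pos.copy()], [radius]
        while radius >= r_min and total_nodes < max_nodes:
            direction = direction + 0.35 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            nxt = pos + step * direction
            if _normalized_radius(nxt, spec.shape)[0] > 0.92:
                # steer back toward the head center
                inward = center - pos
                inward /= np.linalg.norm(inward) + 1e-9
                direction = inward
                nxt = pos + step * direction
                if _normalized_radius(nxt, spec.shape)[0] > 0.95:
                    break
            pos = nxt
            radius *= taper
            points.append(pos.copy())
            radii.append(radius)
            total_nodes += 1
            if rng.random() < spec.branch_prob and radius * 0.75 >= r_min:
                bdir = direction + rng.normal(size=3)
                bdir /= np.linalg.norm(bdir)
                queue.append((pos.copy(), bdir, radius * 0.75))
        if len(points) > 1:
            tree.branches.append(
                (np.asarray(points), np.asarray(radii))
            )
    return tree


def rasterize_tree(tree: VesselTree, shape,
                   voxel_size=(1.0, 1.0, 1.0)) -> BinaryLabelVolume:
    """Label a voxel 1 iff its center lies within the local tube radius
    of any centerline segment (radii in voxel units)."""
    out = np.zeros(shape, dtype=np.uint8)
    for points, radii in tree.branches:
        for i in range(len(points) - 1):
            _mark_segment(out, points[i], points[i + 1],
                          radii[i], radii[i + 1])
    return BinaryLabelVolume(out, voxel_size)


def _mark_segment(out, p0, p1, r0, r1):
    rmax = max(r0, r1)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - rmax - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(np.maximum(p0, p1) + rmax + 1).astype(int) + 1,
        np.asarray(out.shape),
    )
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij"
    )
    pts = np.stack(grids, axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist = np.linalg.norm(pts - closest, axis=-1)
    radius = r0 + t * (r1 - r0)
    region = out[tuple(slice(a, b) for a, b in zip(lo, hi))]
    region[dist <= radius] = 1


def _ellipsoid_mask(shape, center, semi_axes):
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                        indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def synthesize_volume(labels: BinaryLabelVolume, spec: PhantomSpec,
                      seed: int) -> Volume:
    """Paint intensities: air exterior, ellipsoidal tissue head, bright
    skull shell, bright vessels, bright unlabelled distractors, plus
    Gaussian noise clipped at zero."""
    rng = np.random.default_rng(seed)
    shape = spec.shape
    center = (np.asarray(shape) - 1) / 2.0
    head_ax = _head_radius(shape)
    head = _ellipsoid_mask(shape, center, head_ax)
    shell = _ellipsoid_mask(shape, center, head_ax * 1.12) & ~head

    img = np.full(shape, spec.air_intensity, dtype=np.float64)
    img[shell] = spec.skull_intensity
    img[head] = spec.tissue_intensity

    lab = labels.data.astype(bool)
    for _ in range(spec.n_distractors):
        nr = rng.uniform(0.55, 1.05)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = center + direction * nr * head_ax
        pos = np.clip(pos, 3, np.asarray(shape) - 4)
        axes = rng.uniform(1.5, 4.0, size=3)
        blob = _ellipsoid_mask(shape, pos, axes)
        img[blob & ~lab] = spec.distractor_intensity

    img[lab] = spec.vessel_intensity
    img += rng.normal(0.0, spec.noise_sigma, size=shape)
    np.clip(img, 0.0, None, out=img)
    return Volume(img.astype(np.float32), spec.voxel_size)


def generate_phantom(spec: PhantomSpec, seed: int
                     ) -> tuple[Volume, BinaryLabelVolume]:
    """One phantom pair: trees are added until the labelled vessel
    fraction of the head reaches the spec's target (capped)."""
    rng = np.random.default_rng(seed)
    head_voxels = int(
        _ellipsoid_mask(
            spec.shape, (np.asarray(spec.shape) - 1) / 2.0,
            _head_radius(spec.shape)
        ).sum()
    )
    lab = np.zeros(spec.shape, dtype=np.uint8)
    trees = 0
    # at least n_trees trees; keep adding until the target vessel
    # fraction of the head is reached (capped at 4x n_trees)
    while trees < 4 * spec.n_trees:
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = generate_vessel_tree(spec, tree_seed)
        lab |= rasterize_tree(tree, spec.shape, spec.voxel_size).data
        trees += 1
        frac = lab.sum() / head_voxels
        if trees >= spec.n_trees and frac >= spec.target_vessel_fraction:
            break
    labels = BinaryLabelVolume(lab, spec.voxel_size)
    volume = synthesize_volume(labels, spec, int(rng.integers(0, 2**31 - 1)))
    return volume, labels


def generate_dataset(n: int, spec: PhantomSpec, seed: int,
                     n_sources: int = 2, out_dir=None
                     ) -> list[tuple[Volume, BinaryLabelVolume, str]]:
    """Generate `n` independent phantom pairs, round-robin-tagged across
    synthetic source cohorts; optionally written as NIfTI pairs with a
    manifest CSV."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    dataset = []
    for i in range(n):
        source = f"site_{chr(ord('a') + i % n_sources)}"
        v, lab = generate_phantom(spec, int(child_seeds[i]))
        dataset.append((v, lab, source))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        head = _ellipsoid_mask(
            spec.shape, (np.asarray(spec.shape) - 1) / 2.0,
            _head_radius(spec.shape)
        )
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "source", "seed", "vessel_fraction"])
            for i, (v, lab, source) in enumerate(dataset):
                pid = f"phantom_{i:03d}"
                write_volume(v, out_dir / f"{pid}_tof.nii.gz")
                write_volume(lab, out_dir / f"{pid}_label.nii.gz")
                frac = float(lab.data.sum() / head.sum())
                writer.writerow([pid, source, int(child_seeds[i]),
                                 f"{frac:.6f}"])
    return dataset
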
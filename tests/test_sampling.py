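import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bravenet.sampling import (
    centers_to_csv,
    compute_heuristic_mask,
    extract_patch,
    extract_sample,
    make_cv_splits,
    sample_patch_centers,
    splits_from_json,
    splits_to_json,
)
from bravenet.volume_io import BinaryLabelVolume, Volume


def _brute_force_mask(data, window, threshold):
    """Triple-loop box mean with replicate padding; window [i-w//2, i+w-1-w//2]."""
    lo = window // 2
    hi = window - 1 - lo
    padded = np.pad(data.astype(float), ((lo, hi),) * 3, mode="edge")
    out = np.zeros(data.shape, dtype=np.uint8)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                mean = padded[i:i + window, j:j + window, k:k + window].mean()
                out[i, j, k] = mean > threshold
    return out


class TestHeuristicMask:
    def test_constant_zero_gives_empty_mask(self):
        v = Volume(np.zeros((20, 20, 20)))
        assert compute_heuristic_mask(v).data.sum() == 0

    def test_constant_bright_gives_full_mask(self):
        v = Volume(np.full((20, 20, 20), 100.0))
        assert compute_heuristic_mask(v).data.all()

    def test_matches_brute_force_box_mean(self):
        data = np.zeros((12, 12, 12))
        data[3:8, 2:9, 4:10] = 160.0
        v = Volume(data)
        mask = compute_heuristic_mask(v, window=4, threshold=10.0)
        np.testing.assert_array_equal(mask.data,
                                      _brute_force_mask(data, 4, 10.0))

    def test_bright_cube_matches_brute_force_default_window(self):
        data = np.zeros((32, 32, 32))
        data[8:24, 8:24, 8:24] = 160.0
        v = Volume(data)
        mask = compute_heuristic_mask(v, window=16, threshold=10.0)
        # independent oracle: box sums via cumulative sums on an
        # edge-padded array
        lo, hi = 8, 7
        padded = np.pad(data, ((lo, hi),) * 3, mode="edge")
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, (16, 16, 16)
        )
        oracle = windows.mean(axis=(-1, -2, -3)) > 10.0
        np.testing.assert_array_equal(mask.data, oracle.astype(np.uint8))

    def test_threshold_monotonicity(self, small_phantom):
        v, _ = small_phantom
        masks = [compute_heuristic_mask(v, threshold=t).data
                 for t in (5.0, 10.0, 40.0)]
        assert (masks[1] <= masks[0]).all()
        assert (masks[2] <= masks[1]).all()

    def test_window_larger_than_volume_rejected(self):
        with pytest.raises(ValueError, match="window"):
            compute_heuristic_mask(Volume(np.zeros((8, 32, 32))), window=16)


class TestSamplePatchCenters:
    def _pair(self, shape=(16, 16, 8), n_vessel=20, seed=5):
        rng = np.random.default_rng(seed)
        lab = np.zeros(shape, dtype=np.uint8)
        idx = rng.choice(np.prod(shape), size=n_vessel, replace=False)
        lab.reshape(-1)[idx] = 1
        mask = np.ones(shape, dtype=np.uint8)
        return BinaryLabelVolume(lab), BinaryLabelVolume(mask)

    def test_unconstrained_when_fraction_zero(self):
        lab, mask = self._pair()
        mask.data[:8] = 0
        centers = sample_patch_centers(lab, mask, n=10, vessel_fraction=0.0,
                                       seed=1)
        assert len(centers) == 10
        assert all(mask.data[c] == 1 for c in centers)

    def test_all_vessel_with_replacement(self):
        lab, mask = self._pair(n_vessel=2)
        centers = sample_patch_centers(lab, mask, n=4, vessel_fraction=1.0,
                                       seed=2)
        assert len(centers) == 4
        assert all(lab.data[c] == 1 for c in centers)
        assert len(set(centers)) <= 2  # duplicates required

    def test_exact_vessel_centric_quota(self, small_phantom):
        v, lab = small_phantom
        mask = compute_heuristic_mask(v)
        centers = sample_patch_centers(lab, mask, n=2000,
                                       vessel_fraction=0.5, seed=3)
        assert len(centers) == 2000
        n_vessel = sum(int(lab.data[c]) for c in centers)
        assert n_vessel == 1000
        assert all(mask.data[c] == 1 for c in centers)

    def test_reproducible_under_seed(self, small_phantom):
        v, lab = small_phantom
        mask = compute_heuristic_mask(v)
        a = sample_patch_centers(lab, mask, n=50, seed=7)
        b = sample_patch_centers(lab, mask, n=50, seed=7)
        assert a == b

    def test_centers_csv_serialization(self, tmp_path):
        lab, mask = self._pair(n_vessel=5)
        centers = sample_patch_centers(lab, mask, n=6, vessel_fraction=0.5,
                                       seed=4)
        path = tmp_path / "centers.csv"
        centers_to_csv(path, "vol01", centers, lab)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "id,x,y,z,is_vessel_centric"
        assert len(lines) == 7
        assert sum(int(l.split(",")[-1]) for l in lines[1:]) == 3

    def test_error_cases(self):
        lab, mask = self._pair(n_vessel=0)
        with pytest.raises(ValueError, match="vessel"):
            sample_patch_centers(lab, mask, n=4, vessel_fraction=0.5, seed=0)
        empty = BinaryLabelVolume(np.zeros((16, 16, 8), dtype=np.uint8))
        with pytest.raises(ValueError, match="mask"):
            sample_patch_centers(lab, empty, n=4, vessel_fraction=0.0, seed=0)


class TestExtractPatch:
    def test_central_crop_equals_subgrid(self, rng):
        data = rng.normal(size=(32, 32, 16))
        v = Volume(data)
        patch = extract_patch(v, (16, 16, 8), (8, 8, 4))
        np.testing.assert_array_equal(patch, data[12:20, 12:20, 6:10])

    def test_corner_center_pads_leading_half(self, rng):
        data = rng.normal(size=(16, 16, 8)) + 10.0
        patch = extract_patch(Volume(data), (0, 0, 0), (8, 8, 4),
                              pad_value=-1)
        assert (patch[:4] == -1).all()
        assert (patch[:, :4] == -1).all()
        assert (patch[:, :, :2] == -1).all()
        np.testing.assert_array_equal(patch[4:, 4:, 2:], data[:4, :4, :2])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cx=st.integers(0, 31), cy=st.integers(0, 31), cz=st.integers(0, 15)
    )
    def test_nesting_consistency(self, cx, cy, cz):
        rng = np.random.default_rng(99)
        data = rng.normal(size=(32, 32, 16))
        v = Volume(data)
        big = extract_patch(v, (cx, cy, cz), (16, 16, 8))
        small = extract_patch(v, (cx, cy, cz), (8, 8, 4))
        np.testing.assert_array_equal(big[4:12, 4:12, 2:6], small)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError, match="center"):
            extract_patch(Volume(np.zeros((8, 8, 8))), (8, 0, 0), (4, 4, 4))

    def test_extract_sample_shapes(self, small_phantom):
        v, lab = small_phantom
        s = extract_sample(v, lab, (24, 24, 8), primary_size=(16, 16, 8))
        assert s.primary.shape == (16, 16, 8)
        assert s.context.shape == (32, 32, 16)
        assert s.label.shape == (16, 16, 8)


class TestCvSplits:
    def test_reproduces_study_cohort_arithmetic(self):
        splits = make_cv_splits({"A": 74, "B": 9, "C": 181}, folds=4,
                                val_fraction=0.15, seed=0)
        for s in splits:
            assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) \
                == (170, 29, 65)
        tested = [i for s in splits for i in s.test_ids]
        assert len(tested) == len(set(tested)) == 260

    def test_single_small_cohort(self):
        splits = make_cv_splits({"A": 4}, folds=4, val_fraction=0.0, seed=1)
        for s in splits:
            assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) \
                == (3, 0, 1)

    def test_floor_rules_two_cohorts(self):
        splits = make_cv_splits({"A": 8, "B": 8}, folds=4, val_fraction=0.25,
                                seed=2)
        for s in splits:
            assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) \
                == (9, 3, 4)

    def test_partition_and_conservation(self):
        sizes = {"A": 7, "B": 13, "C": 5}
        folds = 4
        splits = make_cv_splits(sizes, folds=folds, val_fraction=0.2, seed=3)
        universe = {i for s in splits
                    for i in s.train_ids + s.val_ids + s.test_ids}
        expected_tested = sum(c // folds for c in sizes.values()) * folds
        tested = [i for s in splits for i in s.test_ids]
        assert len(tested) == len(set(tested)) == expected_tested
        assert expected_tested <= len(universe)
        for s in splits:
            groups = [set(s.train_ids), set(s.val_ids), set(s.test_ids)]
            assert sum(len(g) for g in groups) == len(universe)
            assert set.union(*groups) == universe

    def test_deterministic_and_json_roundtrip(self):
        a = make_cv_splits({"A": 10, "B": 6}, seed=9)
        b = make_cv_splits({"A": 10, "B": 6}, seed=9)
        assert splits_to_json(a) == splits_to_json(b)
        back = splits_from_json(splits_to_json(a))
        assert back[2].test_ids == a[2].test_ids
        assert back[0].source_of == a[0].source_of

    def test_bad_val_fraction_rejected(self):
        with pytest.raises(ValueError, match="val_fraction"):
            make_cv_splits({"A": 8}, val_fraction=1.0, seed=0)
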
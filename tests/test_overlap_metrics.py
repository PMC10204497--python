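"""Overlap statistics against brute-force voxel-count and distance oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mrsipipe import (BinaryMask, VolumeGrid, combined_biomarkers,
                      difference_map, hausdorff_mm, overlap_report)
from mrsipipe.errors import UndefinedMetricError

from conftest import random_mask_pair


def brute_force_stats(a: BinaryMask, b: BinaryMask) -> dict:
    """Independent voxel-counting oracle for every set-based statistic."""
    na = sum(1 for v in a.data.ravel() if v)
    nb = sum(1 for v in b.data.ravel() if v)
    ni = sum(1 for x, y in zip(a.data.ravel(), b.data.ravel()) if x and y)
    nu = na + nb - ni
    return {
        "total_overlap": ni / nb if nb else 0.0,
        "jaccard": ni / nu,
        "dice": 2 * ni / (na + nb),
        "volume_similarity": 2 * (na - nb) / (na + nb),
        "volume_change_signed": (nb - na) / na if na else None,
    }


def brute_force_hausdorff(a: BinaryMask, b: BinaryMask, mode="symmetric"):
    """All-pairs world-distance oracle."""
    pa = a.index_to_world(np.argwhere(a.data))
    pb = b.index_to_world(np.argwhere(b.data))
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    d_ab = d.min(axis=1).max()
    if mode == "directed":
        return float(d_ab)
    return float(max(d_ab, d.min(axis=0).max()))


def box_mask(shape, slc, spacing=(1, 1, 1)):
    data = np.zeros(shape, dtype=bool)
    data[slc] = True
    return BinaryMask(data, spacing)


class TestOverlapReport:
    def test_identical_masks(self, rng):
        a, _ = random_mask_pair(rng)
        if not a.data.any():
            a.data[0, 0, 0] = True
        r = overlap_report(a, a.with_data(a.data.copy()))
        assert r.total_overlap == r.jaccard == r.dice == 1.0
        assert r.volume_similarity == 0.0
        assert r.volume_change_signed == 0.0
        assert r.direction == "unchanged"
        assert r.hausdorff_mm == 0.0

    def test_disjoint_masks(self):
        a = box_mask((10, 10, 10), np.s_[0:2, 0:2, 0:2])
        b = box_mask((10, 10, 10), np.s_[6:8, 6:8, 6:8])
        r = overlap_report(a, b)
        assert r.total_overlap == r.jaccard == r.dice == 0.0

    def test_worked_example_counts(self):
        """1000- and 4960-voxel masks intersecting in 353 voxels at 1 mm
        reproduce the published Jaccard 0.063 and Dice 0.118."""
        shape = (40, 40, 40)
        a = np.zeros(shape, dtype=bool)
        b = np.zeros(shape, dtype=bool)
        a.ravel()[:1000] = True
        b.ravel()[1000 - 353:1000 - 353 + 4960] = True
        r = overlap_report(BinaryMask(a), BinaryMask(b))
        assert round(r.jaccard, 3) == 0.063
        assert round(r.dice, 3) == 0.118
        assert r.volume_change_signed == pytest.approx(3.96)
        assert r.direction == "increase"

    def test_dice_jaccard_identity_every_report(self, rng):
        for _ in range(50):
            a, b = random_mask_pair(rng)
            r = overlap_report(a, b)
            assert r.dice == pytest.approx(2 * r.jaccard / (1 + r.jaccard),
                                           abs=1e-9)
            assert r.jaccard <= r.dice <= 1.0
            assert r.intersection_cc <= min(r.vol_a_cc, r.vol_b_cc) + 1e-12
            assert r.union_cc == pytest.approx(
                r.vol_a_cc + r.vol_b_cc - r.intersection_cc)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            a, b = random_mask_pair(rng, max_side=12)
            r = overlap_report(a, b)
            expected = brute_force_stats(a, b)
            for key, val in expected.items():
                got = getattr(r, key)
                if val is None:
                    assert got is None
                else:
                    assert got == val, key

    def test_swap_symmetry(self, rng):
        a, b = random_mask_pair(rng)
        while not (a.data.any() and b.data.any()):
            a, b = random_mask_pair(rng)
        r1, r2 = overlap_report(a, b), overlap_report(b, a)
        assert r1.jaccard == r2.jaccard
        assert r1.dice == r2.dice
        assert r1.hausdorff_mm == r2.hausdorff_mm
        assert r1.volume_similarity == -r2.volume_similarity
        ni = np.count_nonzero(a.data & b.data)
        assert r2.total_overlap == pytest.approx(
            ni / np.count_nonzero(a.data))

    def test_translation_invariance(self, rng):
        """Set statistics are unchanged under a common lattice translation."""
        a = box_mask((12, 12, 12), np.s_[2:5, 2:5, 2:5])
        b = box_mask((12, 12, 12), np.s_[3:7, 3:6, 2:5])
        r1 = overlap_report(a, b)
        shift = lambda m: BinaryMask(np.roll(m.data, (2, 1, 3), axis=(0, 1, 2)),
                                     m.spacing)
        r2 = overlap_report(shift(a), shift(b))
        for f in ("total_overlap", "jaccard", "dice", "volume_similarity",
                  "hausdorff_mm"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f))

    def test_both_empty_is_an_error(self):
        empty = BinaryMask(np.zeros((4, 4, 4), bool))
        with pytest.raises(UndefinedMetricError):
            overlap_report(empty, empty.with_data(empty.data.copy()))

    def test_empty_b_warns_total_overlap_zero(self):
        a = box_mask((6, 6, 6), np.s_[1:3, 1:3, 1:3])
        empty = BinaryMask(np.zeros((6, 6, 6), bool))
        with pytest.warns(UserWarning):
            r = overlap_report(a, empty)
        assert r.total_overlap == 0.0
        assert r.direction == "decrease"
        assert math.isinf(r.hausdorff_mm)

    def test_empty_a_volume_change_missing(self):
        empty = BinaryMask(np.zeros((6, 6, 6), bool))
        b = box_mask((6, 6, 6), np.s_[1:3, 1:3, 1:3])
        r = overlap_report(empty, b)
        assert r.volume_change_signed is None
        assert r.total_overlap == 0.0

    def test_volume_similarity_range(self):
        a = box_mask((20, 4, 4), np.s_[0:1, 0:1, 0:1])
        b = box_mask((20, 4, 4), np.s_[1:20, :, :])
        r = overlap_report(a, b)
        assert -2.0 <= r.volume_similarity < 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    masks=hnp.arrays(np.bool_, st.tuples(st.integers(2, 8), st.integers(2, 8),
                                         st.integers(2, 8), st.just(2))),
    spacing=st.tuples(*[st.floats(0.5, 3.0) for _ in range(3)]),
)
def test_overlap_identities_hold_for_arbitrary_masks(masks, spacing):
    """Dice-Jaccard identity, bounds, and union arithmetic for any pair."""
    a = BinaryMask(masks[..., 0], spacing)
    b = BinaryMask(masks[..., 1], spacing)
    if not (a.data.any() or b.data.any()):
        return
    r = overlap_report(a, b)
    assert abs(r.dice - 2 * r.jaccard / (1 + r.jaccard)) < 1e-9
    assert 0.0 <= r.jaccard <= r.dice <= 1.0
    assert -2.0 <= r.volume_similarity <= 2.0
    assert r.union_cc == pytest.approx(r.vol_a_cc + r.vol_b_cc
                                       - r.intersection_cc)
    r_swapped = overlap_report(b, a)
    assert r_swapped.jaccard == r.jaccard
    assert r_swapped.volume_similarity == -r.volume_similarity


class TestHausdorff:
    def test_two_point_axis_distance(self):
        a = box_mask((8, 8, 8), np.s_[1:2, 1:2, 1:2])
        b = box_mask((8, 8, 8), np.s_[4:5, 1:2, 1:2])
        assert hausdorff_mm(a, b) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        a = box_mask((8, 8, 8), np.s_[1:2, 1:2, 1:2], spacing=(2, 1, 1))
        b = box_mask((8, 8, 8), np.s_[4:5, 1:2, 1:2], spacing=(2, 1, 1))
        assert hausdorff_mm(a, b) == pytest.approx(6.0)

    def test_directed_vs_symmetric(self):
        big = box_mask((10, 10, 10), np.s_[2:8, 2:8, 2:8])
        small = box_mask((10, 10, 10), np.s_[4:6, 4:6, 4:6])
        d_small_big = hausdorff_mm(small, big, "directed")
        d_big_small = hausdorff_mm(big, small, "directed")
        assert d_small_big == 0.0
        assert hausdorff_mm(small, big) == d_big_small

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(40):
            a, b = random_mask_pair(rng, max_side=10)
            if not (a.data.any() and b.data.any()):
                continue
            for mode in ("directed", "symmetric"):
                assert hausdorff_mm(a, b, mode) == pytest.approx(
                    brute_force_hausdorff(a, b, mode), abs=1e-6)

    def test_empty_operand_errors(self):
        a = box_mask((4, 4, 4), np.s_[0:1, 0:1, 0:1])
        with pytest.raises(UndefinedMetricError):
            hausdorff_mm(a, BinaryMask(np.zeros((4, 4, 4), bool)))


class TestDifferenceMap:
    def setup_method(self):
        self.support = BinaryMask(np.ones((5, 5, 5), bool))

    def test_identical_maps_zero(self):
        r = VolumeGrid(np.random.default_rng(2).random((5, 5, 5)))
        dm = difference_map(r, r.with_data(r.data.copy()), self.support)
        assert np.all(dm.data == 0)

    def test_worsening_voxel_negative(self):
        pre = VolumeGrid(np.full((5, 5, 5), 1.0))
        mid_data = np.full((5, 5, 5), 1.0)
        mid_data[2, 2, 2] = 3.0  # ratio rose: new abnormality, "red"
        dm = difference_map(pre, VolumeGrid(mid_data), self.support)
        assert dm.data[2, 2, 2] < 0
        assert dm.data[0, 0, 0] == 0

    def test_antisymmetric_under_swap(self, rng):
        pre = VolumeGrid(rng.random((5, 5, 5)))
        mid = VolumeGrid(rng.random((5, 5, 5)))
        d1 = difference_map(pre, mid, self.support, 1.3, 0.8)
        d2 = difference_map(mid, pre, self.support, 0.8, 1.3)
        np.testing.assert_allclose(d1.data, -d2.data)

    def test_zero_outside_support(self, rng):
        sup = BinaryMask(rng.random((5, 5, 5)) < 0.5)
        pre = VolumeGrid(rng.random((5, 5, 5)))
        mid = VolumeGrid(rng.random((5, 5, 5)))
        dm = difference_map(pre, mid, sup)
        assert np.all(dm.data[~sup.data] == 0)

    def test_rejects_nonpositive_normalizer(self):
        r = VolumeGrid(np.ones((5, 5, 5)))
        with pytest.raises(ValueError):
            difference_map(r, r, self.support, normalizer_pre=0.0)


class TestCombinedBiomarkers:
    def test_direct_products(self):
        a = box_mask((12, 12, 12), np.s_[0:2, 0:4, 0:4])   # 32 voxels
        b = box_mask((12, 12, 12), np.s_[0:3, 0:4, 0:4])   # 48 voxels
        r = overlap_report(a, b)
        combos = dict(combined_biomarkers(r))
        assert combos["dice_x_direction"] == pytest.approx(r.dice)
        assert combos["dice_x_change_pct"] == pytest.approx(r.dice * 50.0)
        assert combos["jaccard_x_direction"] == pytest.approx(r.jaccard)

    def test_unchanged_volume_gives_zero(self):
        a = box_mask((8, 8, 8), np.s_[0:2, 0:2, 0:2])
        b = box_mask((8, 8, 8), np.s_[1:3, 0:2, 0:2])
        r = overlap_report(a, b)
        combos = dict(combined_biomarkers(r))
        for name, val in combos.items():
            assert val == 0.0, name

    def test_worked_example_sign_product(self):
        """Dice 0.118 with ~+400% growth combines to +0.118 by direction."""
        shape = (40, 40, 40)
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a.ravel()[:1000] = True
        b.ravel()[647:5607] = True
        r = overlap_report(BinaryMask(a), BinaryMask(b))
        combos = dict(combined_biomarkers(r))
        assert combos["dice_x_direction"] == pytest.approx(0.118, abs=5e-4)
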
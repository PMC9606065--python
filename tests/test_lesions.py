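"""Lesion quantification, PERCIST, IoU matching and detection aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from petsynth.grid import VolumeGrid
from petsynth.lesions import (
    PEAK_SPHERE_RADIUS_MM,
    LiverReference,
    compare_groups,
    detection_report,
    label_lesions,
    lesion_records,
    lesion_stats,
    liver_reference,
    match_lesions,
    percist_measurable,
    read_lesions,
    suv_difference_table,
    suv_peak,
)
from petsynth.phantom import ORGAN_LABELS

SPACING = (3.0, 3.3, 3.3)


def _labels(arr):
    return VolumeGrid(np.asarray(arr, dtype=np.int32), spacing=SPACING, is_label=True)


class TestLabelLesions:
    def test_two_disjoint_blobs(self):
        m = np.zeros((8, 8, 8), dtype=np.int32)
        m[1:3, 1:3, 1:3] = 1
        m[5:7, 5:7, 5:7] = 1
        labels, k = label_lesions(_labels(m))
        assert k == 2
        assert set(np.unique(labels.values)) == {0, 1, 2}

    def test_empty_mask(self):
        labels, k = label_lesions(_labels(np.zeros((4, 4, 4))))
        assert k == 0
        assert labels.values.max() == 0

    @pytest.mark.parametrize(
        "offset", [(0, 0, 1), (0, 1, 1), (1, 1, 1)], ids=["face", "edge", "corner"]
    )
    def test_26_connectivity_merges_all_adjacency_cases(self, offset):
        m = np.zeros((4, 4, 4), dtype=np.int32)
        m[1, 1, 1] = 1
        m[1 + offset[0], 1 + offset[1], 1 + offset[2]] = 1
        _, k = label_lesions(_labels(m))
        assert k == 1

    def test_labels_ordered_by_descending_volume(self):
        m = np.zeros((10, 10, 10), dtype=np.int32)
        m[0:2, 0:2, 0:2] = 1  # 8 voxels
        m[6:10, 6:10, 6:10] = 1  # 64 voxels
        labels, k = label_lesions(_labels(m))
        assert k == 2
        assert (labels.values == 1).sum() == 64
        assert (labels.values == 2).sum() == 8


class TestSuvPeak:
    def test_uniform_region_returns_its_value(self):
        img = VolumeGrid(np.full((20, 20, 20), 5.0), spacing=SPACING)
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[8:12, 8:12, 8:12] = True
        assert suv_peak(img, mask) == pytest.approx(5.0)

    def test_single_hot_voxel_matches_brute_force_enumeration(self):
        shape = (20, 20, 20)
        img_arr = np.ones(shape)
        center = (10, 10, 10)
        img_arr[center] = 10.0
        img = VolumeGrid(img_arr, spacing=SPACING)
        mask = np.zeros(shape, dtype=bool)
        mask[8:13, 8:13, 8:13] = True
        # brute force: count voxel centers within the 1-cm^3 sphere radius
        n = 0
        for dz, dy, dx in itertools.product(range(-4, 5), repeat=3):
            d2 = (dz * 3.0) ** 2 + (dy * 3.3) ** 2 + (dx * 3.3) ** 2
            if d2 <= PEAK_SPHERE_RADIUS_MM**2:
                n += 1
        expected = (10.0 + (n - 1) * 1.0) / n
        assert suv_peak(img, mask) == pytest.approx(expected)

    def test_argmax_tie_resolves_to_lowest_index(self):
        shape = (30, 30, 30)
        img_arr = np.zeros(shape)
        img_arr[5, 5, 5] = 7.0
        img_arr[20, 20, 20] = 7.0  # tie, higher index
        img = VolumeGrid(img_arr, spacing=SPACING)
        mask = np.zeros(shape, dtype=bool)
        mask[5, 5, 5] = mask[20, 20, 20] = True
        # sphere around (5,5,5) also catches nothing else; same for the other
        # center, so the values only differ through deterministic tie-breaks
        v1 = suv_peak(img, mask)
        img_arr2 = img_arr.copy()
        img_arr2[20, 20, 20] = 0.0
        v2 = suv_peak(VolumeGrid(img_arr2, spacing=SPACING), mask)
        assert v1 == pytest.approx(v2)

    def test_boundary_sphere_sets_clipped_flag(self):
        img = VolumeGrid(np.ones((6, 6, 6)), spacing=SPACING)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0, 0, 0] = True
        val, clipped = suv_peak(img, mask, return_clipped=True)
        assert clipped
        assert val == pytest.approx(1.0)


class TestLiverReference:
    def test_uniform_liver(self):
        img = VolumeGrid(np.full((20, 20, 20), 2.5), spacing=SPACING)
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[4:16, 4:16, 4:16] = True
        ref = liver_reference(img, mask)
        assert ref.liver_mean == pytest.approx(2.5)
        assert ref.liver_std == pytest.approx(0.0)
        assert "sphere" in ref.voi

    def test_small_liver_falls_back_to_whole_mask(self):
        vals = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2, 2, 2:4] = True
        vals[2, 2, 2] = 2.0
        vals[2, 2, 3] = 3.0
        ref = liver_reference(VolumeGrid(vals, spacing=SPACING), mask)
        assert "whole-liver" in ref.voi
        assert ref.liver_mean == pytest.approx(2.5)
        assert ref.liver_std == pytest.approx(0.5)

    def test_voi_inside_liver_on_phantom(self, small_truth, small_pair):
        fulltime, _, truth = small_pair
        liver = truth.organ_labels.values == ORGAN_LABELS["liver"]
        ref = liver_reference(fulltime, liver)
        assert "sphere" in ref.voi  # default liver can host the 3-cm VOI
        assert ref.liver_mean > 0

    def test_empty_mask_rejected(self):
        img = VolumeGrid(np.ones((4, 4, 4)), spacing=SPACING)
        with pytest.raises(ValueError, match="empty"):
            liver_reference(img, np.zeros((4, 4, 4), dtype=bool))


class TestPercist:
    def test_threshold_arithmetic_and_strictness(self):
        ref = LiverReference(2.0, 0.5)
        assert ref.threshold == pytest.approx(4.0)
        assert percist_measurable(4.1, ref)
        assert not percist_measurable(4.0, ref)  # strictly greater than
        assert not percist_measurable(3.9, ref)

    def test_zero_std(self):
        ref = LiverReference(2.0, 0.0)
        assert ref.threshold == pytest.approx(3.0)

    def test_monotone_in_peak_and_liver_stats(self):
        ref_lo = LiverReference(1.5, 0.2)
        ref_hi = LiverReference(2.5, 0.8)
        for peak in np.linspace(0, 10, 41):
            if percist_measurable(peak, ref_hi):
                assert percist_measurable(peak, ref_lo)


class TestLesionStats:
    def test_volume_from_voxel_count(self):
        img = VolumeGrid(np.ones((10, 10, 10)) * 3.0, spacing=SPACING)
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        flat = np.unravel_index(np.arange(100), (10, 10, 10))
        labels[flat] = 1
        organs = _labels(np.full((10, 10, 10), ORGAN_LABELS["other"]))
        stats = lesion_stats(img, _labels(labels), organs, LiverReference(2.5, 0.3))
        assert stats[0].volume_ml == pytest.approx(100 * 0.03267, abs=1e-3)

    def test_uniform_lesion_covering_sphere(self):
        arr = np.ones((24, 24, 24))
        labels = np.zeros((24, 24, 24), dtype=np.int32)
        labels[6:18, 6:18, 6:18] = 1  # large uniform block, hosts the sphere
        arr[labels == 1] = 6.0
        arr[12, 12, 12] = 6.0 + 1e-9  # unique hottest voxel at the center
        img = VolumeGrid(arr, spacing=SPACING)
        organs = _labels(np.full((24, 24, 24), ORGAN_LABELS["liver"]))
        s = lesion_stats(img, _labels(labels), organs, LiverReference(1.0, 0.0))[0]
        assert s.suv_mean == pytest.approx(6.0)
        assert s.suv_max == pytest.approx(6.0)
        assert s.suv_peak == pytest.approx(6.0)
        assert s.organ == "liver"
        assert s.percist_measurable  # 6 > 1.5

    def test_mean_never_exceeds_max_on_random_lesions(self, rng):
        img = VolumeGrid(rng.uniform(0, 20, (12, 12, 12)), spacing=SPACING)
        labels = np.zeros((12, 12, 12), dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 1
        labels[7:10, 7:10, 7:10] = 2
        organs = _labels(np.full((12, 12, 12), ORGAN_LABELS["lung"]))
        for s in lesion_stats(img, _labels(labels), organs, LiverReference(2.0, 0.2)):
            assert s.suv_mean <= s.suv_max + 1e-9


class TestMatchLesions:
    def test_identical_masks_full_iou(self):
        m = np.zeros((8, 8, 8), dtype=np.int32)
        m[1:3, 1:3, 1:3] = 1
        m[5:7, 5:7, 5:7] = 2
        res = match_lesions(_labels(m), _labels(m))
        assert all(r.detected and r.iou == 1.0 for r in res)

    def test_disjoint_masks_no_detection(self):
        a = np.zeros((8, 8, 8), dtype=np.int32)
        b = np.zeros((8, 8, 8), dtype=np.int32)
        a[1:3, 1:3, 1:3] = 1
        b[5:7, 5:7, 5:7] = 1
        res = match_lesions(_labels(a), _labels(b))
        assert len(res) == 1 and not res[0].detected and res[0].iou == 0.0

    def test_highest_iou_candidate_selected(self):
        ref = np.zeros((4, 10, 10), dtype=np.int32)
        ref[1, 2:7, 2:7] = 1  # 25 voxels
        pred = np.zeros((4, 10, 10), dtype=np.int32)
        pred[1, 2:7, 2:4] = 1  # overlap 10
        pred[1, 2:7, 4:7] = 2  # overlap 15
        res = match_lesions(_labels(ref), _labels(pred))
        # label_lesions ordering is irrelevant here; ids are given directly
        assert res[0].matched_pred_id == 2
        assert res[0].iou == pytest.approx(15 / 25)

    def test_agrees_with_all_pairs_brute_force(self, rng):
        for trial in range(5):
            r = np.random.default_rng(100 + trial)
            ref = r.integers(0, 4, (7, 7, 7)).astype(np.int32)
            pred = r.integers(0, 4, (7, 7, 7)).astype(np.int32)
            res = {m.ref_lesion_id: m for m in match_lesions(_labels(ref), _labels(pred))}
            for rid in np.unique(ref[ref > 0]):
                rset = set(map(tuple, np.argwhere(ref == rid)))
                best_iou, best_pid = 0.0, None
                for pid in np.unique(pred[pred > 0]):
                    pset = set(map(tuple, np.argwhere(pred == pid)))
                    iou = len(rset & pset) / len(rset | pset)
                    if iou > best_iou:
                        best_iou, best_pid = iou, int(pid)
                assert res[rid].iou == pytest.approx(best_iou)
                if best_iou > 0:
                    assert res[rid].matched_pred_id == best_pid


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        u, p = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.8

    def test_exact_small_sample_by_enumeration(self):
        # fully separated groups of 3: U = 0, exact two-sided p = 2/20
        u, p = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        # independent enumeration over all C(6,3) label assignments
        pooled = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        count_extreme = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            u_ab = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
                1 for x in a for y in b if x == y
            )
            if min(u_ab, 9 - u_ab) <= 0:
                count_extreme += 1
        assert p == pytest.approx(count_extreme / 20)

    def test_u1_plus_u2_identity(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        u1, _ = compare_groups(a, b)
        u2, _ = compare_groups(b, a)
        assert u1 + u2 == pytest.approx(len(a) * len(b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestSuvDifferenceTable:
    def _stats(self, suvs, organ="liver"):
        from petsynth.lesions import LesionStats

        return [
            LesionStats(i, organ, 1.0, s, s + 1.0, s + 0.5, True)
            for i, s in enumerate(suvs)
        ]

    def test_identical_images_zero_differences(self):
        s = self._stats([2.0, 4.0, 6.0])
        table = suv_difference_table(s, self._stats([2.0, 4.0, 6.0]))
        row = table[table["organ"] == "all"].iloc[0]
        assert row["suv_mean_diff"] == 0.0 and row["suv_mean_sd"] == 0.0

    def test_uniform_shift_gives_mean_one_sd_zero(self):
        s_full = self._stats([2.0, 4.0, 6.0])
        s_synth = self._stats([1.0, 3.0, 5.0])
        table = suv_difference_table(s_full, s_synth)
        row = table[table["organ"] == "all"].iloc[0]
        assert row["suv_mean_diff"] == pytest.approx(1.0)
        assert row["suv_mean_sd"] == pytest.approx(0.0)

    def test_single_lesion_sd_zero_and_id_mismatch_rejected(self):
        s = self._stats([5.0])
        table = suv_difference_table(s, self._stats([4.0]))
        assert table[table["organ"] == "all"].iloc[0]["suv_mean_sd"] == 0.0
        other = self._stats([4.0])
        other[0].lesion_id = 99
        with pytest.raises(ValueError, match="ids"):
            suv_difference_table(s, other)


class TestDetectionReport:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["patient", "organ", "percist", "detected"])

    def test_all_detected_gives_unit_rates(self):
        rows = [
            ("p1", "bones", True, True),
            ("p1", "lung", False, True),
            ("p2", "liver", True, True),
        ]
        patients = pd.DataFrame(
            {"patient": ["p1", "p2"], "ref_positive": [True, True], "pred_positive": [True, True]}
        )
        rep = detection_report(self._table(rows), patients)
        assert rep.rate("lesion", "all") == 1.0
        assert rep.rate("patient", "percist") == 1.0
        assert rep.sensitivity == 1.0

    def test_stratum_totals_partition_all(self):
        rows = [("p1", "bones", True, True)] * 3 + [("p1", "lung", False, False)] * 2
        rep = detection_report(self._table(rows))
        ll = rep.lesion_level
        al = ll[(ll["stratum"] == "all") & (ll["organ"] == "all")].iloc[0]
        pe = ll[(ll["stratum"] == "percist") & (ll["organ"] == "all")].iloc[0]
        np_ = ll[(ll["stratum"] == "non_percist") & (ll["organ"] == "all")].iloc[0]
        assert pe["total"] + np_["total"] == al["total"] == 5
        assert al["detected"] == 3

    def test_organ_level_any_lesion_semantics(self):
        rows = [
            ("p1", "bones", True, False),
            ("p1", "bones", True, True),  # cell (p1, bones) detected
            ("p2", "bones", True, False),  # cell (p2, bones) missed
        ]
        rep = detection_report(self._table(rows))
        assert rep.rate("organ", "all", "bones") == pytest.approx(0.5)
        assert rep.rate("lesion", "all", "bones") == pytest.approx(1 / 3)

    def test_specificity_from_lesion_free_patients(self):
        rows = [("p1", "liver", True, True)]
        patients = pd.DataFrame(
            {
                "patient": ["p1", "n1", "n2"],
                "ref_positive": [True, False, False],
                "pred_positive": [True, True, False],  # n1 is a false positive
            }
        )
        rep = detection_report(self._table(rows), patients)
        assert rep.specificity == pytest.approx(0.5)
        assert rep.n_negative_patients == 2

    def test_unknown_organ_rejected(self):
        with pytest.raises(ValueError, match="organ"):
            detection_report(self._table([("p1", "spleen", True, True)]))


class TestSurrogateReader:
    def test_finds_hot_lesions_and_ignores_uniform_background(self, small_pair):
        fulltime, extreme, truth = small_pair
        labels, n = read_lesions(fulltime, truth.organ_labels, truth.body_mask.values)
        assert n >= 2  # both seeded lesions are well above background
        matches = match_lesions(truth.lesion_labels, labels)
        assert all(m.detected for m in matches)
        # a noise-free lesion-less image yields no reads
        from petsynth.phantom import PhantomSpec, make_phantom, simulate_pet

        spec = PhantomSpec(shape=(16, 32, 32))
        tr = make_phantom(spec)
        clean = simulate_pet(tr, 1.0, spec, seed=0, noise=False)
        _, n0 = read_lesions(clean, tr.organ_labels, tr.body_mask.values)
        assert n0 == 0
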
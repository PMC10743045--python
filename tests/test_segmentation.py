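"""Segmentation methods, Jaccard agreement and the cohort exclusion rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radrobust.phantoms import PhantomSpec, generate_phantom
from radrobust.segmentation import (
    METHODS,
    RoiBox,
    SegmentationResult,
    SegmentationSet,
    agreement_matrix,
    jaccard,
    region_grow_segment,
    roi_from_mask,
    segment_case,
    threshold_segment,
)


class TestJaccard:
    def test_identity_disjoint_and_enumerated_overlap(self):
        a = np.zeros((10, 1, 1), dtype=bool)
        b = np.zeros((10, 1, 1), dtype=bool)
        a[:4] = True
        assert jaccard(a, a) == 1.0
        b[5:8] = True
        assert jaccard(a, b) == 0.0
        b[:] = False
        b[2:5] = True  # |X|=4, |Y|=3, |X∩Y|=2 -> 2/5
        assert jaccard(a, b) == pytest.approx(0.4)

    def test_errors(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            jaccard(a, a)
        with pytest.raises(ValueError, match="mismatch"):
            jaccard(np.ones((3, 3, 3), bool), np.ones((4, 4, 4), bool))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_identity_characterization(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((6, 6, 6)) < 0.4
        y = rng.random((6, 6, 6)) < 0.4
        if not (x.any() or y.any()):
            return
        assert jaccard(x, y) == jaccard(y, x)
        if x.any():
            assert (jaccard(x, x.copy()) == 1.0) and ((jaccard(x, y) == 1.0) == np.array_equal(x, y))

    def test_monotone_under_erosion(self):
        from scipy import ndimage

        spec = PhantomSpec(noise_sd=0.0, heterogeneity_amplitude=0.0)
        mask = generate_phantom(spec, 0).truth_mask
        js = []
        for r in (1, 2, 3):
            eroded = ndimage.binary_erosion(mask, iterations=r)
            js.append(jaccard(mask, eroded))
        assert js[0] > js[1] > js[2]


class TestThresholdSegment:
    def test_fraction_one_selects_unique_maximum(self):
        rng = np.random.default_rng(0)
        img = rng.random((10, 10, 10))
        img[5, 5, 5] = 2.0
        roi = RoiBox((2, 2, 2), (9, 9, 9))
        res = threshold_segment(img, roi, fraction=1.0)
        assert res.success and res.mask.sum() == 1 and res.mask[5, 5, 5]

    def test_noiseless_sphere_matches_direct_threshold(self, noiseless_case):
        roi = roi_from_mask(noiseless_case.truth_mask)
        res = threshold_segment(noiseless_case.image, roi, fraction=0.4)
        # threshold = 0.4 * 10 = 4; rim (6) and core (10) pass, background (1) fails
        expected = np.zeros_like(noiseless_case.truth_mask)
        expected[roi.slices] = noiseless_case.image[roi.slices] >= 4.0
        assert res.success
        np.testing.assert_array_equal(res.mask, expected)

    def test_roi_without_lesion_fails(self, noiseless_case):
        roi = RoiBox((0, 0, 0), (5, 5, 5))  # background corner
        res = threshold_segment(noiseless_case.image, roi, 0.4)
        assert not res.success

    def test_constant_roi_flagged(self):
        roi = RoiBox((1, 1, 1), (5, 5, 5))
        res = threshold_segment(np.ones((8, 8, 8)), roi, 0.5)
        assert not res.success and "constant" in res.reason


class TestRegionGrowSegment:
    def test_noiseless_sphere_recovered(self, noiseless_case):
        roi = roi_from_mask(noiseless_case.truth_mask)
        res = region_grow_segment(noiseless_case.image, roi)
        assert res.success
        assert jaccard(res.mask, noiseless_case.truth_mask) >= 0.85

    def test_noisy_sphere_recovered(self, noisy_case):
        roi = roi_from_mask(noisy_case.truth_mask)
        res = region_grow_segment(noisy_case.image, roi)
        assert res.success
        assert jaccard(res.mask, noisy_case.truth_mask) >= 0.85

    def test_uniform_image_fails(self):
        roi = RoiBox((2, 2, 2), (12, 12, 12))
        assert not region_grow_segment(np.ones((16, 16, 16)), roi).success

    def test_deterministic(self, noisy_case):
        roi = roi_from_mask(noisy_case.truth_mask)
        a = region_grow_segment(noisy_case.image, roi, iterations=40)
        b = region_grow_segment(noisy_case.image, roi, iterations=40)
        np.testing.assert_array_equal(a.mask, b.mask)


def _segset(subject_id, masks, failed=()):
    s = SegmentationSet(subject_id=subject_id)
    for m, mask in masks.items():
        s.add(m, SegmentationResult(mask, True))
    for m in failed:
        s.add(m, SegmentationResult(None, False, "failed"))
    return s


class TestAgreementMatrix:
    def test_identical_masks_give_ones(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        sets = [_segset(f"S{i}", {m: mask for m in METHODS}) for i in range(3)]
        am = agreement_matrix(sets)
        np.testing.assert_allclose(am.values, 1.0)

    def test_mean_of_pairwise_jaccards(self):
        # two subjects engineered to give Jaccards 0.5 and 0.7 for one pair
        def bar(n):
            m = np.zeros((20, 1, 1), dtype=bool)
            m[:n] = True
            return m

        s1 = _segset("a", {"manual": bar(10), "thresholding": bar(5), "region_growing": bar(10)})
        s2 = _segset("b", {"manual": bar(10), "thresholding": bar(7), "region_growing": bar(10)})
        am = agreement_matrix([s1, s2])
        assert am.pair("manual", "thresholding") == pytest.approx(0.6)
        assert am.pair("manual", "region_growing") == 1.0
        # symmetry and unit diagonal
        np.testing.assert_allclose(am.values, am.values.T)
        np.testing.assert_allclose(np.diag(am.values), 1.0)

    def test_exclusion_rule_drops_incomplete_subjects(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        good = [_segset(f"S{i}", {m: mask for m in METHODS}) for i in range(3)]
        bad = _segset("S9", {"manual": mask, "thresholding": mask}, failed=("region_growing",))
        am = agreement_matrix(good + [bad])
        assert am.n_subjects == 3

    def test_error_when_no_complete_subject(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        bad = _segset("S0", {"manual": mask}, failed=("thresholding", "region_growing"))
        with pytest.raises(ValueError):
            agreement_matrix([bad])


class TestCohortSegmentation:
    def test_all_methods_succeed_on_default_phantoms(self, segmentations):
        assert all(s.complete() for s in segmentations)

    def test_semiautomatic_pair_agrees_at_least_as_well_as_manual_pairs(self, segmentations):
        am = agreement_matrix(segmentations)
        semi = am.pair("thresholding", "region_growing")
        assert semi >= am.pair("manual", "thresholding")
        assert semi >= am.pair("manual", "region_growing")

    def test_manual_stand_in_differs_from_truth(self, small_cohort, segmentations):
        by_id = {s.subject_id: s for s in segmentations}
        diffs = [
            jaccard(by_id[c.subject_id].masks["manual"], c.truth_mask) for c in small_cohort
        ]
        assert np.mean(diffs) < 1.0
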
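import itertools

import numpy as np
import pytest

from dcecad.core import ContractError, DcePhaseStack
from dcecad.crop import crop_to_window
from dcecad.segmentation import (
    BinaryMask,
    DegenerateHistogramError,
    _histogram,
    intersect_masks,
    otsu_multilevel,
    segment_slice,
    top_class_mask,
)


def brute_force_max_variance(img, nbins=256, n_thr=4):
    """Exhaustive maximum of the between-class objective over all cut tuples.

    Cuts need only be considered at occupied histogram bins (cutting inside
    an empty gap yields the same partition), so the search is exact.
    """
    hist = _histogram(img, nbins)
    nz = np.nonzero(hist)[0]
    p = hist / hist.sum()
    x = np.arange(nbins)
    best = -1.0
    for cuts in itertools.combinations(nz[:-1], n_thr):
        edges = [0] + [c + 1 for c in cuts] + [nbins]
        v = sum(
            (p[a:b] * x[a:b]).sum() ** 2 / w
            for a, b in zip(edges[:-1], edges[1:])
            if (w := p[a:b].sum()) > 0
        )
        best = max(best, v)
    return best


def achieved_variance(img, thresholds, nbins=256):
    hist = _histogram(img, nbins)
    p = hist / hist.sum()
    x = np.arange(nbins)
    cut_bins = np.round(np.asarray(thresholds) * nbins).astype(int) - 1
    edges = [0] + [c + 1 for c in cut_bins] + [nbins]
    return sum(
        (p[a:b] * x[a:b]).sum() ** 2 / w
        for a, b in zip(edges[:-1], edges[1:])
        if (w := p[a:b].sum()) > 0
    )


class TestOtsuMultilevel:
    def test_five_flat_blocks_separated_exactly(self):
        img = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 200).reshape(5, 200)
        thr = otsu_multilevel(img)
        labels = np.digitize(img, thr)
        for row, lbl in enumerate([0, 1, 2, 3, 4]):
            assert np.all(labels[row] == lbl)

    def test_four_thresholds_give_five_classes(self, rng):
        thr = otsu_multilevel(rng.random((32, 32)), n_thresholds=4)
        assert len(thr) == 4          # five classes between/around them
        assert np.all(np.diff(thr) > 0)

    def test_matches_exhaustive_search_on_quantized_images(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            img = rng.integers(0, 16, size=(32, 32)) / 15.0
            thr = otsu_multilevel(img)
            assert achieved_variance(img, thr) == pytest.approx(
                brute_force_max_variance(img), abs=1e-10
            )

    def test_agrees_with_reference_implementation(self, rng):
        from skimage.filters import threshold_multiotsu

        img = rng.random((64, 64)) ** 2
        ours = otsu_multilevel(img)
        ref = threshold_multiotsu(img, classes=5, nbins=256)
        # conventions differ by at most one bin width
        assert np.allclose(ours, ref, atol=1.5 / 256)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_multilevel(np.full((8, 8), 0.5))

    def test_too_few_gray_levels_rejected(self):
        img = np.repeat([0.0, 1.0], 32).reshape(8, 8)
        with pytest.raises(DegenerateHistogramError):
            otsu_multilevel(img, n_thresholds=4)


class TestTopClassMask:
    def test_only_brightest_block_selected(self):
        img = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 200).reshape(5, 200)
        mask = top_class_mask(img, otsu_multilevel(img))
        assert mask.values[4].all() and not mask.values[:4].any()

    def test_empty_mask_is_legal(self):
        img = np.array([[0.1, 0.2], [0.3, 0.4]])
        mask = top_class_mask(img, np.array([0.9]))
        assert not mask.values.any()

    def test_count_non_increasing_in_threshold(self, rng):
        img = rng.random((32, 32))
        counts = [top_class_mask(img, np.array([t])).values.sum()
                  for t in (0.2, 0.5, 0.8)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_empty_thresholds_rejected(self, rng):
        with pytest.raises(ContractError):
            top_class_mask(rng.random((4, 4)), np.array([]))


class TestIntersectMasks:
    def _mask(self, values):
        return BinaryMask(values=values, provenance="otsu2")

    def test_idempotent(self, rng):
        a = self._mask(rng.random((8, 8)) > 0.5)
        assert np.array_equal(intersect_masks(a, a).values, a.values)

    def test_empty_absorbs(self, rng):
        a = self._mask(rng.random((8, 8)) > 0.5)
        empty = self._mask(np.zeros((8, 8), bool))
        assert not intersect_masks(a, empty).values.any()

    def test_overlapping_rectangles(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[2:7, 2:7] = True
        b[4:9, 4:9] = True
        out = intersect_masks(self._mask(a), self._mask(b))
        expect = np.zeros((10, 10), bool)
        expect[4:7, 4:7] = True
        assert np.array_equal(out.values, expect)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            intersect_masks(self._mask(np.zeros((4, 4), bool)),
                            self._mask(np.zeros((5, 5), bool)))


class TestSegmentSlice:
    def test_intersection_subset_of_per_phase_masks(self, single_phantom):
        stack, _ = single_phantom
        res = segment_slice(stack)
        for k, m in res.per_phase_masks.items():
            assert np.all(res.mask.values <= m.values)

    def test_phantom_lesions_overlap_intersection(self, single_phantom):
        stack, truth = single_phantom
        res = segment_slice(stack)
        full = res.mask_full_frame(stack.shape)
        for lesion in truth.lesions:
            if lesion.area_px >= 15:
                overlap = (full & lesion.mask).sum() / lesion.area_px
                assert overlap >= 0.5

    def test_structure_enhancing_only_in_phase3_is_excluded(self):
        """A region absent from the phase-2 subtraction cannot enter I_otsu."""
        rng = np.random.default_rng(0)
        base = np.zeros((64, 64))
        # two tissue blocks on an air background, joined by a deep band so
        # the median-column depth scan keeps the whole anatomy in the crop
        base[8:41, 8:29] = 0.1 + 0.02 * rng.random((33, 21))
        base[8:41, 36:57] = 0.1 + 0.02 * rng.random((33, 21))
        base[44:51, 8:57] = 0.12
        early = np.zeros_like(base)
        early[10:18, 10:18] = 0.55 + 0.05 * rng.random((8, 8))   # both phases
        late = np.zeros_like(base)
        late[10:18, 40:48] = 0.55 + 0.05 * rng.random((8, 8))    # phase 3 only
        tissue = base > 0
        phases = [base]
        for enh in (early, early, early + late, early + late):
            p = base + enh
            p[tissue] += 0.02 * rng.random(int(tissue.sum()))    # mild uptake
            phases.append(p)
        stack = DcePhaseStack(phases=phases)
        res = segment_slice(stack)
        full = res.mask_full_frame(stack.shape)
        assert not full[10:18, 40:48].any()
        assert full[10:18, 10:18].sum() >= 32
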
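"""Thresholding, cluster detection, intensity partitioning and Grubbs rule."""

import numpy as np
import pytest
from scipy import stats

from synaptraffick.puncta import (
    ChannelImage,
    DegenerateHistogramError,
    RoiSpec,
    detect_clusters,
    estimate_background,
    grubbs_remove_outlier,
    label_synaptic,
    otsu_threshold,
    partition_intensity,
    summarize_cell,
    threshold_mask,
)
from synaptraffick.scenes import make_dendrite_scene
from tests.conftest import well_separated_truth


def img(arr, px=0.1, channel="ch"):
    return ChannelImage(pixels=np.asarray(arr, dtype=float),
                        pixel_size_um=px, channel=channel)


def brute_force_otsu(values):
    """Independent oracle: scan every candidate threshold in pure python."""
    v = sorted(float(x) for x in np.ravel(values))
    candidates = sorted(set(v))
    best_t, best_var = None, -1.0
    n = len(v)
    for t in candidates[1:]:
        lo = [x for x in v if x < t]
        hi = [x for x in v if x >= t]
        w_lo = len(lo) / n
        w_hi = len(hi) / n
        mu_lo = sum(lo) / len(lo)
        mu_hi = sum(hi) / len(hi)
        var_b = w_lo * w_hi * (mu_lo - mu_hi) ** 2
        if var_b > best_var + 1e-15:
            best_var, best_t = var_b, t
    return best_t


class TestThresholdMask:
    def test_zero_image_fixed_threshold_gives_empty_mask(self):
        mask, meta = threshold_mask(img(np.zeros((8, 8))), method="fixed",
                                    fixed_value=1.0)
        assert not mask.any()
        assert meta["threshold"] == 1.0

    def test_otsu_separates_two_level_image(self):
        arr = np.full((10, 10), 10.0)
        arr[3:5, 3:5] = 100.0
        mask, meta = threshold_mask(img(arr), method="otsu")
        np.testing.assert_array_equal(mask, arr == 100.0)
        assert meta["threshold"] == 100.0

    def test_fixed_threshold_at_max_selects_argmax_only(self):
        arr = np.arange(16, dtype=float).reshape(4, 4)
        mask, _ = threshold_mask(img(arr), method="fixed", fixed_value=15.0)
        assert mask.sum() == 1 and mask[3, 3]

    def test_constant_image_under_otsu_is_degenerate(self, flat_image):
        with pytest.raises(DegenerateHistogramError, match="degenerate"):
            threshold_mask(flat_image, method="otsu")

    def test_fixed_without_value_rejected(self, flat_image):
        with pytest.raises(ValueError, match="fixed_value"):
            threshold_mask(flat_image, method="fixed")

    @pytest.mark.parametrize("seed", range(5))
    def test_otsu_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 256, size=(24, 24)).astype(float)
        assert otsu_threshold(arr) == brute_force_otsu(arr)

    def test_raising_fixed_threshold_never_grows_mask(self):
        rng = np.random.default_rng(7)
        arr = rng.uniform(0, 100, size=(32, 32))
        image = img(arr)
        prev_area = arr.size + 1
        for thr in (10, 30, 50, 70, 90):
            mask, _ = threshold_mask(image, method="fixed", fixed_value=thr)
            assert mask.sum() <= prev_area
            prev_area = mask.sum()


class TestDetectClusters:
    def test_small_component_within_window_kept(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px -> 0.04 um^2 at 0.1 um/px
        cs = detect_clusters(mask, img(np.ones((8, 8))), (0.0, 3.0))
        assert len(cs) == 1
        assert cs.clusters[0].area_um2 == pytest.approx(0.04)

    def test_component_above_size_window_excluded(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[0:20, 0:20] = True  # 400 px = 4 um^2 > 3 um^2
        cs = detect_clusters(mask, img(np.ones((30, 30))), (0.0, 3.0))
        assert len(cs) == 0

    def test_diagonal_pixels_are_one_cluster_under_8_connectivity(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        cs = detect_clusters(mask, img(np.ones((5, 5))), (0.0, 3.0))
        assert len(cs) == 1

    def test_channel_sums_use_unsmoothed_intensities(self):
        arr = np.zeros((6, 6))
        arr[2, 2], arr[2, 3] = 40.0, 60.0
        mask = arr > 0
        cs = detect_clusters(mask, img(arr), (0.0, 3.0))
        c = cs.clusters[0]
        assert c.channel_sum["ch"] == 100.0
        assert c.channel_mean["ch"] == 50.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            detect_clusters(np.zeros((4, 4), dtype=bool), img(np.ones((5, 5))))


class TestLabelSynaptic:
    def _one_cluster(self, pixels, shape=(10, 10)):
        mask = np.zeros(shape, dtype=bool)
        for r, c in pixels:
            mask[r, c] = True
        return detect_clusters(mask, img(np.ones(shape)), (0.0, 3.0))

    def test_contained_cluster_is_synaptic(self):
        rec = self._one_cluster([(4, 4)])
        mark = self._one_cluster([(3, 3), (3, 4), (4, 3), (4, 4), (4, 5)])
        assert label_synaptic(rec, mark).n_synaptic == 1

    def test_disjoint_clusters_are_not_synaptic(self):
        rec = self._one_cluster([(1, 1)])
        mark = self._one_cluster([(8, 8)])
        assert label_synaptic(rec, mark).n_synaptic == 0

    def test_min_overlap_threshold_respected(self):
        rec = self._one_cluster([(4, 4), (4, 5)])
        mark = self._one_cluster([(4, 5), (4, 6)])
        assert label_synaptic(rec, mark, min_overlap_px=1).n_synaptic == 1
        rec2 = self._one_cluster([(4, 4), (4, 5)])
        assert label_synaptic(rec2, mark, min_overlap_px=2).n_synaptic == 0


def full_roi(shape):
    return np.ones(shape, dtype=bool)


class TestPartitionIntensity:
    def test_stated_subtraction_formula(self):
        # total 1000, background_total 100, synaptic (bg-corrected) 400
        arr = np.zeros((10, 10))
        arr[:, :] = 1.0              # background 1/px * 100 px = 100
        arr[0, 0:4] = 101.0          # one synaptic cluster: sum 404 - 4 bg = 400
        arr[5, 0:5] = 101.0          # extrasynaptic signal: 505 - 5 bg = 500
        image = img(arr)
        cs = detect_clusters(arr > 1.0, image, (0.0, 3.0))
        for c in cs.clusters:
            c.synaptic = c.pixel_index[0, 0] == 0
        part = partition_intensity(image, full_roi(arr.shape), cs, background=1.0)
        assert part.total_sum == pytest.approx(1000.0)
        assert part.background_total == pytest.approx(100.0)
        assert part.synaptic_sum == pytest.approx(400.0)
        assert part.extrasynaptic_sum == pytest.approx(500.0)

    def test_zero_background_no_synaptic_gives_extrasynaptic_total(self):
        arr = np.arange(16, dtype=float).reshape(4, 4)
        image = img(arr)
        cs = detect_clusters(np.zeros_like(arr, dtype=bool), image)
        part = partition_intensity(image, full_roi(arr.shape), cs, background=0.0)
        assert part.extrasynaptic_sum == part.total_sum == arr.sum()

    def test_conservation_identity_machine_precision(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            arr = rng.uniform(0, 200, size=(20, 20))
            image = img(arr)
            cs = detect_clusters(arr > 150, image, (0.0, 3.0))
            for c in cs.clusters:
                c.synaptic = True
            bg = float(rng.uniform(0, 5))
            p = partition_intensity(image, full_roi(arr.shape), cs, background=bg)
            assert (p.synaptic_sum + p.extrasynaptic_sum + p.background_total
                    == pytest.approx(p.total_sum, rel=1e-12))

    def test_synaptic_sum_matches_planted_gaussian_integrals(self):
        truth = well_separated_truth(n_synaptic=5, n_extrasynaptic=5)
        images, truth = make_dendrite_scene(truth)
        rec = images["receptor"]
        mark = images["marker"]
        thr = truth.background_level + 1.0
        rec_cs = detect_clusters(rec.pixels >= thr, rec, (0.0, 3.0))
        mark_cs = detect_clusters(mark.pixels >= thr, mark, (0.0, 3.0))
        rec_cs = label_synaptic(rec_cs, mark_cs)
        part = partition_intensity(rec, full_roi(rec.shape), rec_cs,
                                   background=truth.background_level)
        expected = sum(truth.punctum_integral(p) for p in truth.puncta
                       if p.synaptic)
        assert part.synaptic_sum == pytest.approx(expected, rel=0.05)

    def test_oversubtraction_flagged_but_retained(self):
        arr = np.ones((5, 5))
        image = img(arr)
        cs = detect_clusters(np.zeros_like(arr, dtype=bool), image)
        with pytest.warns(UserWarning, match="over-subtraction"):
            p = partition_intensity(image, full_roi(arr.shape), cs,
                                    background=2.0)
        assert p.oversubtracted and p.extrasynaptic_sum < 0

    def test_polygon_roi_restricts_pixels(self):
        arr = np.ones((10, 10))
        image = img(arr)
        roi = RoiSpec(role="dendrite_segment",
                      vertices=((0.0, 0.0), (0.0, 5.0), (5.0, 5.0), (5.0, 0.0)))
        cs = detect_clusters(np.zeros_like(arr, dtype=bool), image)
        p = partition_intensity(image, roi, cs, background=0.0)
        assert p.roi_pixel_count < arr.size
        assert p.total_sum == p.roi_pixel_count


class TestSummarizeCell:
    def test_mean_of_three_rois(self):
        assert summarize_cell([10, 20, 30]) == 20

    def test_single_roi_passthrough(self):
        assert summarize_cell([7]) == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cell([])

    def test_uniform_image_rois_equal_cell_mean(self, flat_image):
        vals = [float(flat_image.pixels[:8, i:i + 8].mean()) for i in range(3)]
        assert summarize_cell(vals) == pytest.approx(vals[0])


class TestGrubbs:
    def test_extreme_point_removed(self):
        # oracle: G = (5-2)/sd = 1.4987 > G_crit(n=4, a=.05) = 1.4812
        vals = [1.0, 1.1, 0.9, 5.0]
        n = 4
        t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))
        g = (5.0 - np.mean(vals)) / np.std(vals, ddof=1)
        assert g > g_crit
        kept, removed = grubbs_remove_outlier(vals, alpha=0.05)
        assert removed == 5.0 and kept == [1.0, 1.1, 0.9]

    def test_symmetric_data_untouched(self):
        kept, removed = grubbs_remove_outlier([1.0, 2.0, 3.0, 4.0, 5.0])
        assert removed is None and len(kept) == 5

    def test_at_most_one_removal_with_two_extremes(self):
        vals = [1.0, 1.1, 0.9, 1.05, 50.0, 60.0]
        kept, removed = grubbs_remove_outlier(vals)
        assert len(kept) >= len(vals) - 1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            grubbs_remove_outlier([1.0, 2.0])

    def test_constant_data_untouched(self):
        kept, removed = grubbs_remove_outlier([2.0, 2.0, 2.0, 2.0])
        assert removed is None


def test_background_estimator_is_median_outside_clusters():
    arr = np.full((10, 10), 5.0)
    arr[0, 0] = 100.0
    image = img(arr)
    cs = detect_clusters(arr > 50, image, (0.0, 3.0))
    assert estimate_background(image, cs) == 5.0
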
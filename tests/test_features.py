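"""IIMV and IIH feature extraction: masks, histograms, peaks, bin selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyhist import (
    HistogramFeature,
    SelectionPolicy,
    bin_correlations,
    build_feature_matrix,
    compute_index,
    detect_peaks,
    equal_mean_distinct_coverage_pair,
    histogram,
    iimv,
    segment_vegetation,
    select_region,
)
from canopyhist.color_index import IndexRaster

from .conftest import make_image


def raster_from(values, index_name="GMRN", rng_range=(-1.0, 1.0)):
    values = np.asarray(values, dtype=np.float64)
    return IndexRaster(
        values=values, valid_mask=np.isfinite(values),
        index_name=index_name, theoretical_range=rng_range,
    )


class TestSegmentVegetation:
    def test_green_red_mixture_split_exactly(self, rng):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        green = rng.random((10, 10)) < 0.5
        px[green, 1] = 255
        px[~green, 0] = 255
        mask = segment_vegetation(make_image(px))
        assert mask.coverage == pytest.approx(green.mean())
        assert np.array_equal(mask.mask, green)

    def test_all_green_full_coverage_with_fixed_threshold(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        px[:, :, 1] = 200
        assert segment_vegetation(make_image(px), threshold=0.0).coverage == 1.0

    def test_threshold_above_max_empties_mask(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        px[:, :, 1] = 200
        assert segment_vegetation(make_image(px), threshold=1.01).coverage == 0.0

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError, match="no valid pixels"):
            segment_vegetation(make_image(np.zeros((3, 3, 3))))


class TestIimv:
    def test_constant_raster(self):
        r = raster_from(np.full((5, 5), 0.3))
        assert iimv(r) == pytest.approx(0.3, abs=1e-15)

    def test_mask_selects_one_population(self):
        from canopyhist.features import VegetationMask

        vals = np.where(np.arange(100).reshape(10, 10) < 50, 0.2, 0.8)
        r = raster_from(vals)
        mask = VegetationMask(mask=vals == 0.2, coverage=0.5, threshold=0.5)
        assert iimv(r, mask) == pytest.approx(0.2, abs=1e-15)

    def test_matches_masked_loop_oracle(self, rng):
        from canopyhist.features import VegetationMask

        vals = rng.uniform(-1, 1, size=(20, 20))
        sel = rng.random((20, 20)) < 0.4
        r = raster_from(vals)
        mask = VegetationMask(mask=sel, coverage=sel.mean(), threshold=0.0)
        acc, n = 0.0, 0
        for i in range(20):
            for j in range(20):
                if sel[i, j]:
                    acc += vals[i, j]
                    n += 1
        assert iimv(r, mask) == pytest.approx(acc / n, abs=1e-12)

    def test_empty_vegetation_mask_falls_back_to_all_valid(self):
        from canopyhist.features import VegetationMask

        r = raster_from(np.full((3, 3), 0.5))
        mask = VegetationMask(mask=np.zeros((3, 3), bool), coverage=0.0, threshold=2.0)
        assert iimv(r, mask) == pytest.approx(0.5)


class TestHistogram:
    def test_constant_raster_single_bin(self):
        h = histogram(raster_from(np.zeros((8, 8))), n_bins=256)
        assert h.percentages.sum() == pytest.approx(100.0, abs=1e-9)
        hot = np.flatnonzero(h.percentages)
        assert len(hot) == 1
        lo, hi = h.bin_edges[hot[0]], h.bin_edges[hot[0] + 1]
        assert lo <= 0.0 < hi
        assert h.percentages[hot[0]] == pytest.approx(100.0)

    def test_two_value_raster_splits_evenly(self):
        vals = np.where(np.arange(64).reshape(8, 8) < 32, 0.5, -0.5)
        h = histogram(raster_from(vals), n_bins=256)
        assert sorted(h.percentages[h.percentages > 0]) == [50.0, 50.0]

    def test_matches_counting_loop_oracle(self, rng):
        vals = rng.uniform(-1, 1, size=(30, 30))
        n_bins = 64
        h = histogram(raster_from(vals), n_bins=n_bins)
        counts = np.zeros(n_bins)
        for v in vals.ravel():
            k = int((v - (-1.0)) / (2.0 / n_bins))
            k = min(k, n_bins - 1)
            counts[k] += 1
        assert np.allclose(h.percentages, 100.0 * counts / counts.sum(), atol=1e-12)

    def test_out_of_range_values_clipped_into_end_bins(self):
        r = raster_from(np.array([[0.5, 9.0]]), index_name="GR", rng_range=(0.0, 5.0))
        h = histogram(r, n_bins=10)
        assert h.percentages[-1] == pytest.approx(50.0)
        assert h.percentages[1] == pytest.approx(50.0)  # 0.5 in [0.5, 1.0) bin

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n_bins=st.integers(2, 300))
    def test_percentages_sum_to_100(self, seed, n_bins):
        vals = np.random.default_rng(seed).uniform(-1, 1, size=(6, 7))
        h = histogram(raster_from(vals), n_bins=n_bins)
        assert h.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_no_valid_pixels_raises(self):
        with pytest.raises(ValueError, match="no valid pixels"):
            histogram(raster_from(np.full((2, 2), np.nan)))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            histogram(raster_from(np.zeros((2, 2))), n_bins=1)


def bump_histogram(centers_heights, n_bins=256, width=6):
    pct = np.zeros(n_bins)
    for c, h in centers_heights:
        for k in range(-width, width + 1):
            pct[c + k] += h * (width + 1 - abs(k))
    pct *= 100.0 / pct.sum()
    edges = np.linspace(-1, 1, n_bins + 1)
    return HistogramFeature(bin_edges=edges, percentages=pct, index_name="GMRN")


class TestDetectPeaks:
    def test_two_bumps_found_at_their_centers(self):
        h = detect_peaks(bump_histogram([(60, 1.0), (180, 0.7)]), smooth_window=5)
        assert h.peak_a_bin == 60
        assert h.peak_b_bin == 180

    def test_single_bump_above_midpoint_is_peak_b(self):
        h = detect_peaks(bump_histogram([(200, 1.0)]))
        assert h.peak_a_bin is None
        assert h.peak_b_bin == 200

    def test_single_bump_below_midpoint_is_peak_a(self):
        h = detect_peaks(bump_histogram([(30, 1.0)]))
        assert h.peak_a_bin == 30
        assert h.peak_b_bin is None

    def test_flat_histogram_flagged_no_peaks(self):
        edges = np.linspace(-1, 1, 65)
        flat = HistogramFeature(
            bin_edges=edges, percentages=np.full(64, 100.0 / 64), index_name="GMRN"
        )
        out = detect_peaks(flat)
        assert out.flat and out.peak_a_bin is None and out.peak_b_bin is None

    def test_close_maxima_collapse_to_positional_assignment(self):
        # two bumps 10 bins apart (< min_separation) count as one mode
        h = detect_peaks(bump_histogram([(170, 1.0), (180, 0.9)]), min_separation=20)
        assert h.peak_a_bin is None
        assert h.peak_b_bin is not None


class TestBinCorrelations:
    def test_linear_and_antilinear_bins(self, rng):
        t = rng.uniform(2, 4, 20)
        H = rng.uniform(0, 5, size=(20, 6))
        H[:, 2] = 2.0 * t + 1.0
        H[:, 4] = -t
        H[:, 5] = 7.0  # constant across samples
        r = bin_correlations(H, t)
        assert r[2] == pytest.approx(1.0, abs=1e-12)
        assert r[4] == pytest.approx(-1.0, abs=1e-12)
        assert r[5] == 0.0

    def test_matches_pearson_oracle(self, rng):
        from scipy.stats import pearsonr

        H = rng.uniform(0, 3, size=(40, 25))
        t = rng.uniform(2, 4, 40)
        r = bin_correlations(H, t)
        for j in range(25):
            assert r[j] == pytest.approx(pearsonr(H[:, j], t).statistic, abs=1e-12)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            bin_correlations(rng.random((2, 4)), np.array([1.0, 2.0]))

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            bin_correlations(rng.random((5, 4)), np.ones(5))


def template_with_peak_b(bin_b=180, n_bins=256):
    edges = np.linspace(-1, 1, n_bins + 1)
    pct = np.zeros(n_bins)
    pct[bin_b] = 100.0
    return HistogramFeature(
        bin_edges=edges, percentages=pct, index_name="GMRN",
        peak_a_bin=60, peak_b_bin=bin_b,
    )


class TestSelectRegion:
    def test_full_window_kept_when_all_correlated(self):
        r = np.full(256, 0.9)
        sel = select_region(
            r, template_with_peak_b(180),
            SelectionPolicy(window=41, r_min=0.5, k_min=8, k_max=41),
        )
        assert sel.bin_indices == list(range(160, 201))

    def test_exact_survivors_kept_when_between_kmin_and_kmax(self):
        r = np.full(256, 0.1)
        r[175:179] = 0.9
        sel = select_region(
            r, template_with_peak_b(180),
            SelectionPolicy(window=41, r_min=0.6, k_min=4, k_max=12),
        )
        assert sel.bin_indices == [175, 176, 177, 178]

    def test_fallback_takes_largest_by_magnitude(self, rng):
        r = rng.uniform(-0.4, 0.4, 256)
        policy = SelectionPolicy(window=41, r_min=0.5, k_min=5, k_max=12)
        sel = select_region(r, template_with_peak_b(180), policy)
        window = list(range(160, 201))
        expected = sorted(sorted(window, key=lambda b: -abs(r[b]))[:5])
        assert sel.bin_indices == expected

    def test_cap_keeps_top_kmax(self):
        r = np.zeros(256)
        r[160:201] = np.linspace(0.5, 0.95, 41)
        sel = select_region(
            r, template_with_peak_b(180),
            SelectionPolicy(window=41, r_min=0.5, k_min=8, k_max=12),
        )
        assert len(sel.bin_indices) == 12
        assert sel.bin_indices == list(range(189, 201))  # the 12 largest r

    def test_global_policy_ignores_peaks(self, rng):
        r = rng.uniform(-1, 1, 256)
        tmpl = template_with_peak_b(180)
        tmpl.peak_a_bin = tmpl.peak_b_bin = None
        sel = select_region(r, tmpl, SelectionPolicy(policy="global_corr", top_k=10))
        expected = sorted(np.argsort(-np.abs(r), kind="stable")[:10].tolist())
        assert sel.bin_indices == expected

    def test_missing_peak_advises_policy_switch(self):
        tmpl = template_with_peak_b(180)
        tmpl.peak_b_bin = None
        with pytest.raises(ValueError, match="global_corr"):
            select_region(np.zeros(256), tmpl)


class TestBuildFeatureMatrix:
    def test_iimv_shape_90_by_6(self, small_cohort):
        fm = build_feature_matrix(small_cohort.records, small_cohort.images, "iimv")
        assert fm.values.shape == (90, 6)
        assert fm.feature_names[0] == "IIMV_GR"

    def test_iih_shape_matches_selection(self, small_cohort):
        from canopyhist.features import BinSelection

        sel = BinSelection(
            index_name="GMRN", bin_indices=list(range(150, 170)),
            per_bin_correlation=[0.0] * 20, target_name="leaf_n",
            bin_edges=np.linspace(-1, 1, 257),
        )
        fm = build_feature_matrix(
            small_cohort.records, small_cohort.images, "iih", selection=sel
        )
        assert fm.values.shape == (90, 20)

    def test_deterministic(self, small_cohort):
        a = build_feature_matrix(small_cohort.records[:6], small_cohort.images, "iimv")
        b = build_feature_matrix(small_cohort.records[:6], small_cohort.images, "iimv")
        assert np.array_equal(a.values, b.values)

    def test_missing_image_listed(self, small_cohort):
        with pytest.raises(ValueError, match=small_cohort.records[0].sample_id):
            build_feature_matrix(small_cohort.records[:3], {}, "iimv")

    def test_iih_requires_selection(self, small_cohort):
        with pytest.raises(ValueError, match="BinSelection"):
            build_feature_matrix(small_cohort.records[:3], small_cohort.images, "iih")


class TestInformationContent:
    def test_equal_means_but_different_histograms(self):
        """A whole-frame mean cannot separate what a histogram separates."""
        img1, img2 = equal_mean_distinct_coverage_pair()
        m1 = iimv(compute_index(img1, "GMRN"))
        m2 = iimv(compute_index(img2, "GMRN"))
        assert abs(m1 - m2) < 1e-3
        h1 = histogram(compute_index(img1, "GMRN"), 256).percentages
        h2 = histogram(compute_index(img2, "GMRN"), 256).percentages
        assert np.max(np.abs(h1 - h2)) > 1.0
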
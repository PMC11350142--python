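"""Month clustering: features, k-means, contiguity, naming, per-pixel pipeline."""

from itertools import combinations

import numpy as np
import pytest

from worldseasons.clustering import (
    SeasonCalendar,
    SeasonLabel,
    build_feature_matrix,
    classify_pixel,
    classify_raster,
    contiguous_partition_oracle,
    enforce_contiguity,
    kmeans_months,
    n_circular_runs,
    name_seasons,
    partition_sse,
)
from worldseasons.climate import PixelClimate, extract_pixel
from worldseasons.params import Params, WeightSet
from worldseasons.synthetic import ArchetypeSpec, make_pixel, make_raster
from worldseasons.zones import Zone


def brute_force_bipartition_sse(X):
    """Minimum SSE over all 2047 nonempty bipartitions of the 12 months."""
    best = np.inf
    for r in range(1, 7):
        for comb in combinations(range(12), r):
            lab = np.zeros(12, int)
            lab[list(comb)] = 1
            best = min(best, partition_sse(X, lab))
    return best


class TestBuildFeatureMatrix:
    def test_zone_dimensions(self, archetype_pixels):
        dims = {
            "arctic": 2, "desert_hot": 2, "temperate": 4, "tropical_unimodal": 3,
        }
        zones = {
            "arctic": Zone.ARCTIC_MONTANE, "desert_hot": Zone.DESERT,
            "temperate": Zone.TEMPERATE, "tropical_unimodal": Zone.TROPICAL,
        }
        for arch, d in dims.items():
            pix, _ = archetype_pixels[arch]
            X = build_feature_matrix(pix, zones[arch])
            assert X.shape == (12, d)

    def test_unweighted_columns_are_zscores(self, archetype_pixels):
        pix, _ = archetype_pixels["arctic"]
        X = build_feature_matrix(pix, Zone.ARCTIC_MONTANE)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, rtol=1e-9)

    def test_sqrt_weight_scaling(self, archetype_pixels):
        pix, _ = archetype_pixels["temperate"]
        w1 = WeightSet(temperate_temperature=1.0)
        w4 = WeightSet(temperate_temperature=4.0)
        X1 = build_feature_matrix(pix, Zone.TEMPERATE, w1)
        X4 = build_feature_matrix(pix, Zone.TEMPERATE, w4)
        # a weight of 4 quadruples the column's squared norm
        assert (X4[:, 0] ** 2).sum() == pytest.approx(4 * (X1[:, 0] ** 2).sum())
        np.testing.assert_allclose(X1[:, 1:], X4[:, 1:])

    def test_all_ones_equals_plain_zscores(self, archetype_pixels):
        pix, _ = archetype_pixels["temperate"]
        ones = WeightSet(
            temperate_temperature=1, temperate_precip_lag=1,
            temperate_temp_lag=1, temperate_ndvi_lag=1,
        )
        X = build_feature_matrix(pix, Zone.TEMPERATE, ones)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, rtol=1e-9)


class TestKmeansMonths:
    def test_separated_blobs(self):
        X = np.zeros((12, 2))
        X[6:] = 10.0
        lab = kmeans_months(X + np.random.default_rng(0).normal(0, 0.1, (12, 2)), 2)
        assert len(set(lab[:6])) == 1 and len(set(lab[6:])) == 1
        assert lab[0] != lab[6]

    def test_k1_single_label(self, rng):
        lab = kmeans_months(rng.normal(size=(12, 2)), 1)
        assert (lab == lab[0]).all()

    def test_degenerate_fallback_flagged(self):
        with pytest.warns(UserWarning, match="single-cluster"):
            lab = kmeans_months(np.ones((12, 3)), 2)
        assert (lab == 0).all()

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(12, 3))
        np.testing.assert_array_equal(
            kmeans_months(X, 4, seed=7), kmeans_months(X, 4, seed=7)
        )

    def test_matches_sklearn_sse(self, rng):
        # independent route: sklearn's k-means should find the same optimum
        from sklearn.cluster import KMeans

        for i in range(20):
            X = rng.normal(size=(12, 2))
            ours = partition_sse(X, kmeans_months(X, 2, seed=i, restarts=50))
            sk = KMeans(n_clusters=2, n_init=50, random_state=i).fit(X)
            theirs = partition_sse(X, sk.labels_)
            assert ours <= theirs + 1e-9

    def test_attains_global_bipartition_optimum(self, rng):
        hits = 0
        for i in range(30):
            X = rng.normal(size=(12, 2))
            sse = partition_sse(X, kmeans_months(X, 2, seed=i, restarts=50))
            if abs(sse - brute_force_bipartition_sse(X)) < 1e-9:
                hits += 1
        assert hits >= 27


class TestContiguousPartitionOracle:
    def test_two_blocks(self):
        X = np.zeros((12, 2))
        X[6:] = 5.0
        lab = contiguous_partition_oracle(X, 2)
        assert len(set(lab[:6])) == 1 and len(set(lab[6:])) == 1
        assert lab[0] != lab[6]

    def test_tie_break_lexicographic(self):
        lab = contiguous_partition_oracle(np.zeros((12, 2)), 2)
        # first cut-set (0, 1): January alone, rest together
        assert lab[0] != lab[1]
        assert len(set(lab[1:])) == 1

    def test_beats_every_contiguous_bipartition(self, rng):
        X = rng.normal(size=(12, 3))
        best = partition_sse(X, contiguous_partition_oracle(X, 2))
        for cut in combinations(range(12), 2):
            lab = np.zeros(12, int)
            a, b = cut
            lab[a:b] = 1
            assert best <= partition_sse(X, lab) + 1e-9

    def test_k4_yields_four_nonempty_arcs(self, rng):
        lab = contiguous_partition_oracle(rng.normal(size=(12, 4)), 4)
        assert len(set(lab)) == 4
        assert n_circular_runs(lab) == 4


class TestEnforceContiguity:
    def test_contiguous_input_unchanged(self, rng):
        lab = np.array([0] * 5 + [1] * 7)
        np.testing.assert_array_equal(enforce_contiguity(lab, rng.normal(size=(12, 2))), lab)

    def test_single_flip_projection(self, rng):
        # one dissenting month inside a clean split: flipping it is optimal
        lab = np.array([0, 0, 0, 0, 0, 1, 0, 0, 1, 1, 1, 1])
        expected = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1])
        X = rng.normal(size=(12, 2))
        np.testing.assert_array_equal(enforce_contiguity(lab, X), expected)

    def test_output_always_contiguous(self, rng):
        for _ in range(50):
            lab = rng.integers(0, 2, 12)
            if len(set(lab)) < 2:
                continue
            out = enforce_contiguity(lab, rng.normal(size=(12, 2)))
            assert n_circular_runs(out) <= len(set(out))

    def test_never_beats_oracle_sse(self, rng):
        for i in range(50):
            X = rng.normal(size=(12, 2))
            lab = enforce_contiguity(kmeans_months(X, 2, seed=i), X)
            oracle_sse = partition_sse(X, contiguous_partition_oracle(X, 2))
            assert partition_sse(X, lab) >= oracle_sse - 1e-9


class TestNameSeasons:
    def test_northern_temperate_ordering(self, archetype_pixels):
        pix, _ = archetype_pixels["temperate"]
        arcs = np.array([0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 0])  # DJF/MAM/JJA/SON
        cal = name_seasons(arcs, pix, Zone.TEMPERATE)
        assert cal.names() == (
            ["winter"] * 2 + ["spring"] * 3 + ["summer"] * 3 + ["autumn"] * 3 + ["winter"]
        )

    def test_southern_hemisphere_mirror(self):
        pix, _ = make_pixel(ArchetypeSpec("temperate", hemisphere="S"))
        arcs = np.array([2, 2, 3, 3, 3, 0, 0, 0, 1, 1, 1, 2])
        cal = name_seasons(arcs, pix, Zone.TEMPERATE)
        assert cal.names()[6] == "winter" and cal.names()[0] == "summer"
        assert cal.names()[9] == "spring" and cal.names()[3] == "autumn"

    def test_tropical_by_rainfall(self, archetype_pixels):
        pix, _ = archetype_pixels["tropical_unimodal"]
        lab = (pix.precip > pix.precip.mean()).astype(int)
        cal = name_seasons(lab, pix, Zone.TROPICAL)
        wet = np.array(cal.names()) == "wet"
        assert wet[lab == 1].all() and not wet[lab == 0].any()

    def test_label_permutation_invariance(self, archetype_pixels):
        pix, _ = archetype_pixels["arctic"]
        lab = np.array([0] * 4 + [1] * 5 + [0] * 3)
        cal_a = name_seasons(lab, pix, Zone.ARCTIC_MONTANE)
        cal_b = name_seasons(1 - lab, pix, Zone.ARCTIC_MONTANE)
        np.testing.assert_array_equal(cal_a.labels, cal_b.labels)


class TestSeasonCalendar:
    def test_zone_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="not allowed"):
            SeasonCalendar(zone=Zone.TROPICAL, labels=np.full(12, int(SeasonLabel.WINTER)))

    def test_noncontiguous_temperate_rejected(self):
        labels = np.array([1, 3, 1, 3, 1, 3, 1, 3, 1, 3, 1, 3], dtype=np.uint8)
        with pytest.raises(ValueError, match="contiguous"):
            SeasonCalendar(zone=Zone.ARCTIC_MONTANE, labels=labels)

    def test_multiple_wet_runs_allowed_in_tropics(self):
        labels = np.array([5, 6, 6, 6, 5, 5, 5, 6, 6, 6, 5, 5], dtype=np.uint8)
        cal = SeasonCalendar(zone=Zone.TROPICAL, labels=labels)
        assert cal.names().count("wet") == 6


class TestClassifyPixel:
    def test_temperate_archetype(self, archetype_pixels):
        pix, truth = archetype_pixels["temperate"]
        cal = classify_pixel(pix)
        assert cal.zone == Zone.TEMPERATE
        names = cal.names()
        assert set(names) == {"winter", "spring", "summer", "autumn"}
        assert names[int(np.argmin(pix.tmid))] == "winter"
        assert names[int(np.argmax(pix.tmid))] == "summer"

    def test_bimodal_tropics_two_wet_runs(self, archetype_pixels):
        pix, _ = archetype_pixels["tropical_bimodal"]
        cal = classify_pixel(pix)
        assert cal.zone == Zone.TROPICAL
        wet_runs = n_circular_runs(cal.labels) // 2
        assert wet_runs == 2

    def test_arctic_two_contiguous_seasons(self, archetype_pixels):
        pix, _ = archetype_pixels["arctic"]
        cal = classify_pixel(pix)
        assert set(cal.names()) == {"winter", "summer"}
        assert n_circular_runs(cal.labels) == 2

    def test_deterministic(self, archetype_pixels):
        pix, _ = archetype_pixels["desert_cold"]
        np.testing.assert_array_equal(
            classify_pixel(pix, seed=3).labels, classify_pixel(pix, seed=3).labels
        )

    def test_affine_invariance_of_clustered_variable(self, archetype_pixels):
        # scaling a clustered variable is absorbed by z-normalization
        pix, _ = archetype_pixels["temperate"]
        scaled = PixelClimate(
            tmin=pix.tmin, tmax=pix.tmax, precip=pix.precip,
            srad=pix.srad, ndvi=pix.ndvi * 2.0 + 0.1, pet=pix.pet,
        )
        np.testing.assert_array_equal(
            classify_pixel(pix).labels, classify_pixel(scaled).labels
        )

    def test_degenerate_temperate_constant_climate(self):
        pix = PixelClimate(
            tmin=np.full(12, 12.0), tmax=np.full(12, 22.0), precip=np.full(12, 50.0),
            srad=np.full(12, 150.0), ndvi=np.full(12, 0.4), pet=np.full(12, 60.0),
        )
        cal = classify_pixel(pix)
        assert cal.zone == Zone.TEMPERATE
        assert len(set(cal.labels.tolist())) == 4  # oracle fallback: 4 nonempty arcs

    def test_spring_warms_faster_than_autumn(self, archetype_pixels):
        pix, _ = archetype_pixels["temperate"]
        names = np.array(classify_pixel(pix).names())
        spring = pix.lag_tmid[names == "spring"].mean()
        autumn = pix.lag_tmid[names == "autumn"].mean()
        assert spring > autumn


class TestClassifyRaster:
    def test_matches_per_pixel_and_zone_sets(self):
        field = np.empty((4, 4), dtype=object)
        field[:2, :2] = "temperate"
        field[:2, 2:] = "tropical_unimodal"
        field[2:, :2] = "desert_hot"
        field[2:, 2:] = "arctic"
        stack, truth_zone, _ = make_raster(4, 4, field, seed=5, noise_sd=0.5)
        sr = classify_raster(stack, seed=1)
        np.testing.assert_array_equal(sr.zones, truth_zone)
        allowed = {1: {7, 8}, 2: {1, 3}, 3: {5, 6}, 4: {1, 2, 3, 4}}
        for r in range(4):
            for c in range(4):
                cell = set(sr.codes[:, r, c].tolist())
                assert cell <= allowed[truth_zone[r, c]]
                cal = classify_pixel(extract_pixel(stack, c, r), seed=1)
                np.testing.assert_array_equal(sr.codes[:, r, c], cal.labels)

    def test_masked_stays_masked(self):
        field = np.full((3, 3), "arctic", dtype=object)
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 1] = False
        stack, _, _ = make_raster(3, 3, field, seed=0, mask=mask)
        sr = classify_raster(stack)
        assert (sr.codes[:, 1, 1] == 0).all()
        assert sr.zones[1, 1] == 0
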
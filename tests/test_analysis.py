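"""Topology/geometry statistics: distributions, moments, shape, Lewis' law."""

import math

import numpy as np
import pytest
from scipy.stats import skew as scipy_skew

from meristemsim import analysis as an
from meristemsim.analysis import ReferenceDistribution

from conftest import hex_rosette, star_polygon


def regular_ngon(n, r=1.0):
    th = 2 * np.pi * np.arange(n) / n
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


class TestNeighborDistribution:
    def test_rosette_single_interior_hexagon(self):
        t = hex_rosette()
        stats = an.compute_stats(t)
        assert stats.n_cells_interior == 1
        assert an.neighbor_distribution(stats.neighbor_counts) == {6: 1.0}

    def test_synthetic_counts(self):
        assert an.neighbor_distribution([5, 6, 6, 7]) == {5: 0.25, 6: 0.5, 7: 0.25}

    def test_distribution_sums_to_one(self, rng):
        counts = rng.integers(4, 9, 300)
        f = an.neighbor_distribution(counts)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)


class TestMoments:
    def test_constant_sample_flagged_zero(self):
        assert an.distribution_moments([6, 6, 6]) == (0.0, 0.0)

    def test_symmetric_three_point(self):
        std, sk = an.distribution_moments([5, 6, 7])
        assert std == pytest.approx(math.sqrt(2 / 3))
        assert sk == pytest.approx(0.0, abs=1e-12)

    def test_skew_sign_matches_brute_force(self):
        # mean 35/6; third central moment = (2*(-5/6)^3 + 3*(1/6)^3 + (7/6)^3)/6 > 0
        sample = [5, 5, 6, 6, 6, 7]
        _, sk = an.distribution_moments(sample)
        assert sk == pytest.approx(float(scipy_skew(sample)))
        assert sk > 0

    def test_left_tailed_sample_negative_skew(self):
        _, sk = an.distribution_moments([4, 5, 6, 6, 6, 6])
        assert sk == pytest.approx(float(scipy_skew([4, 5, 6, 6, 6, 6])))
        assert sk < 0


class TestDeviation:
    def test_zero_for_identical(self):
        ref = an.CUCUMBER_REFERENCE
        assert an.deviation(dict(ref.fractions), ref) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        ref = ReferenceDistribution({5: 0.5, 7: 0.5})
        assert an.deviation({6: 1.0}, ref) == pytest.approx(1.5)

    def test_symmetric_in_arguments(self):
        f = {5: 0.2, 6: 0.5, 7: 0.3}
        ref = ReferenceDistribution({5: 0.4, 6: 0.4, 8: 0.2})
        d1 = an.deviation(f, ref)
        d2 = an.deviation(dict(ref.fractions), ReferenceDistribution(f))
        assert d1 == pytest.approx(d2)

    def test_alternative_metrics(self):
        ref = ReferenceDistribution({5: 0.5, 7: 0.5})
        assert an.deviation({6: 1.0}, ref, metric="l1") == pytest.approx(2.0)
        with pytest.raises(ValueError):
            an.deviation({6: 1.0}, ref, metric="bogus")

    def test_reference_must_normalize(self):
        with pytest.raises(ValueError):
            ReferenceDistribution({5: 0.5, 6: 0.6})


class TestShapeMeasure:
    def test_regular_hexagon_prints_0072(self):
        s = an.shape_measure(regular_ngon(6))
        assert s == pytest.approx(math.sqrt(3) / 24)
        assert round(s, 3) == 0.072

    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert an.shape_measure(sq) == pytest.approx(1 / 16)

    def test_elongated_rectangle_far_below_hexagon(self):
        rect = np.array([[0, 0], [100, 0], [100, 1], [0, 1]], dtype=float)
        assert an.shape_measure(rect) == pytest.approx(100 / 202**2)

    def test_isoperimetric_bound(self, rng):
        """A/P^2 <= 1/(4*pi) for every polygon, approached by many-gons."""
        for _ in range(50):
            poly = star_polygon(rng, n=int(rng.integers(3, 12)))
            assert an.shape_measure(poly) <= an.SHAPE_MAX + 1e-12
        assert an.shape_measure(regular_ngon(256)) == pytest.approx(
            an.SHAPE_MAX, rel=1e-3)

    def test_scale_invariance(self):
        assert an.shape_measure(regular_ngon(6, r=37.0)) == pytest.approx(
            an.shape_measure(regular_ngon(6, r=0.01)))


class TestAngleDistributions:
    def test_all_hexagon_ideal_is_point_mass(self):
        ideal = an.ideal_angle_distribution({6: 1.0})
        assert ideal == {2 * math.pi / 3: 1.0}

    def test_vertex_count_weighting(self):
        ideal = an.ideal_angle_distribution({5: 0.5, 6: 0.5})
        assert ideal[3 * math.pi / 5] == pytest.approx(5 / 11)
        assert ideal[2 * math.pi / 3] == pytest.approx(6 / 11)

    def test_histograms_normalized(self, rng):
        h = an.angle_histogram(rng.uniform(0.3, 3.0, 500))
        assert h.sum() == pytest.approx(1.0, abs=1e-12)
        hi = an.ideal_angle_histogram({5: 0.4, 6: 0.4, 7: 0.2})
        assert hi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_total_variation_bounds(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        assert an.total_variation(p, p) == 0.0
        assert an.total_variation(p, q) == 1.0


class TestLewisLaw:
    def _stats(self, counts, areas):
        counts = np.asarray(counts)
        areas = np.asarray(areas, dtype=float)
        return an.SnapshotStats(
            neighbor_counts=counts, areas=areas,
            shape_measures=np.full(len(counts), 0.06),
            angles=np.array([2.0]),
            normalized_areas=areas / areas.mean(),
            n_cells_total=len(counts), n_cells_interior=len(counts))

    def test_uniform_hexagon_lattice_normalizes_to_unity(self):
        df = an.lewis_law(self._stats([6] * 10, [3.7] * 10))
        assert df.loc[0, "mean_area"] == pytest.approx(1.0)

    def test_reference_line_consistent_with_normalization(self):
        df = an.lewis_law(self._stats([6] * 10, [1.0] * 10))
        assert df.attrs["ref_slope"] * 6 + df.attrs["ref_intercept"] == pytest.approx(1.0)

    def test_fitted_slope_recovers_linear_data(self):
        counts = [5] * 10 + [6] * 10 + [7] * 10
        areas = [0.8] * 10 + [1.0] * 10 + [1.2] * 10
        df = an.lewis_law(self._stats(counts, areas))
        assert df.attrs["slope"] == pytest.approx(0.2, abs=1e-9)


class TestAggregate:
    def _stats_with_counts(self, counts):
        counts = np.asarray(counts)
        return an.SnapshotStats(
            neighbor_counts=counts, areas=np.ones(len(counts)),
            shape_measures=np.full(len(counts), 0.06), angles=np.array([2.0]),
            normalized_areas=np.ones(len(counts)),
            n_cells_total=len(counts), n_cells_interior=len(counts))

    def test_identical_snapshots_zero_error(self):
        s = self._stats_with_counts([5, 6, 7, 6])
        out = an.aggregate([s, s, s])
        assert out["std_err"] == pytest.approx(0.0)

    def test_sample_std_convention(self):
        # snapshots with stds sqrt(2/3) and 0 -> sample std of the pair
        s1 = self._stats_with_counts([5, 6, 7])
        s2 = self._stats_with_counts([6, 6, 6])
        out = an.aggregate([s1, s2])
        vals = [math.sqrt(2 / 3), 0.0]
        assert out["std_mean"] == pytest.approx(np.mean(vals))
        assert out["std_err"] == pytest.approx(np.std(vals, ddof=1))
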
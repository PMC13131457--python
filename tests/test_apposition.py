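"""Edge distances, apposition bins, Monte Carlo nulls and group tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from evquant.apposition import (
    DistanceRecord,
    edge_to_edge_distances,
    fisher_exact_contact,
    mann_whitney,
    monte_carlo_null,
    pooled_enrichment,
    summarize_apposition,
)
from evquant.errors import AnalysisError, InputError
from evquant.imaging import BinaryMask
from evquant.synthetic import worked_example_field

from conftest import brute_force_edge_nm, particles_from_labels, random_sparse_particles


def _random_field(rng, shape=(64, 64)):
    from skimage import morphology

    mito = rng.random(shape) < 0.01
    mito = morphology.dilation(mito, morphology.disk(2))
    if not mito.any():
        mito[shape[0] // 2, shape[1] // 2] = True
    particles, _ = random_sparse_particles(rng, shape=shape)
    return particles, BinaryMask(mito, 65.0, role="mitochondria")


class TestEdgeDistances:
    def test_overlapping_particle_is_contact(self):
        mito = np.zeros((16, 16), bool)
        mito[4:8, 4:8] = True
        labels = np.zeros((16, 16), np.int32)
        labels[5, 5] = 1
        ps = particles_from_labels(labels)
        rec = edge_to_edge_distances(ps, BinaryMask(mito, 65.0))[0]
        assert rec.edge_distance_nm == 0.0 and rec.in_contact

    def test_worked_example_gaps_1_to_5_at_31nm(self):
        ps, mito = worked_example_field()
        recs = edge_to_edge_distances(ps, mito)
        assert [r.edge_distance_nm for r in recs] == [31.0, 62.0, 93.0, 124.0, 155.0]
        assert np.mean([r.edge_distance_nm for r in recs]) == 93.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        particles, mito = _random_field(rng)
        recs = edge_to_edge_distances(particles, mito)
        for p, rec in zip(particles, recs):
            expect = brute_force_edge_nm(p.coords, mito.mask, 65.0)
            assert rec.edge_distance_nm == pytest.approx(expect, abs=1e-9)

    def test_edge_at_most_centroid_distance(self, rng):
        particles, mito = _random_field(rng)
        for rec in edge_to_edge_distances(particles, mito):
            assert rec.edge_distance_nm <= rec.centroid_distance_nm + 1e-9

    def test_rigid_transform_invariance(self):
        mito = np.zeros((48, 48), bool)
        mito[10:14, 8:30] = True
        labels = np.zeros((48, 48), np.int32)
        labels[20:22, 12:14] = 1
        ps = particles_from_labels(labels)
        base = edge_to_edge_distances(ps, BinaryMask(mito, 65.0))[0].edge_distance_nm
        # translation
        ps_t = particles_from_labels(np.roll(labels, (5, 7), (0, 1)))
        mito_t = BinaryMask(np.roll(mito, (5, 7), (0, 1)), 65.0)
        assert edge_to_edge_distances(ps_t, mito_t)[0].edge_distance_nm == base
        # 90 degree co-rotation
        ps_r = particles_from_labels(np.rot90(labels).copy())
        mito_r = BinaryMask(np.rot90(mito).copy(), 65.0)
        assert edge_to_edge_distances(ps_r, mito_r)[0].edge_distance_nm == base

    def test_pixel_size_scales_distances_linearly(self, rng):
        particles, mito = _random_field(rng)
        d1 = [r.edge_distance_nm
              for r in edge_to_edge_distances(particles, mito, pixel_size_nm=65.0)]
        d2 = [r.edge_distance_nm
              for r in edge_to_edge_distances(particles, mito, pixel_size_nm=130.0)]
        np.testing.assert_allclose(d2, np.array(d1) * 2.0)

    def test_empty_organelle_is_error(self, rng):
        particles, _ = random_sparse_particles(rng)
        with pytest.raises(AnalysisError):
            edge_to_edge_distances(particles, BinaryMask(np.zeros((64, 64), bool), 65.0))


class TestSummaries:
    def _recs(self, edges):
        return [
            DistanceRecord(i, e, e + 10.0, e == 0.0) for i, e in enumerate(edges)
        ]

    def test_all_contact(self):
        s = summarize_apposition(self._recs([0.0] * 5))
        assert s.cumulative_fractions == (1.0,) * 5

    def test_contact_fraction_60_percent(self):
        edges = [0.0] * 30 + [400.0] * 20
        s = summarize_apposition(self._recs(edges))
        assert s.contact_fraction == 0.6
        assert s.n_particles == 50

    def test_matches_threshold_counting_oracle(self, rng):
        edges = rng.uniform(0, 1500, 40)
        edges[rng.random(40) < 0.3] = 0.0
        s = summarize_apposition(self._recs(list(edges)))
        for t, f in zip(s.thresholds_nm, s.cumulative_fractions):
            assert f == pytest.approx(np.mean(edges <= t))
        assert np.all(np.diff(s.cumulative_fractions) >= 0)

    def test_empty_records_error(self):
        with pytest.raises(InputError):
            summarize_apposition([])


class TestMonteCarlo:
    def _setup(self, seed=0, shape=(96, 96)):
        rng = np.random.default_rng(seed)
        particles, mito = _random_field(rng, shape=shape)
        roi = BinaryMask(np.ones(shape, bool), 65.0, role="cell_roi")
        return particles, mito, roi

    def test_same_seed_bit_reproducible(self):
        particles, mito, roi = self._setup()
        a = monte_carlo_null(particles, mito, roi, n_iterations=200, seed=11)
        b = monte_carlo_null(particles, mito, roi, n_iterations=200, seed=11)
        assert a.empirical_p == b.empirical_p
        assert a.null_mean == b.null_mean
        assert [x.expected_fraction for x in a.bins] == [
            x.expected_fraction for x in b.bins
        ]

    def test_maximal_proximity_hits_add_one_floor(self):
        # all particles overlap the organelle; ROI mostly far away
        shape = (128, 128)
        mito = np.zeros(shape, bool)
        mito[60:68, 60:68] = True
        labels = np.zeros(shape, np.int32)
        for i, c in enumerate(range(61, 66), start=1):
            labels[62, c] = i
        ps = particles_from_labels(labels)
        roi = BinaryMask(np.ones(shape, bool), 65.0)
        mc = monte_carlo_null(ps, BinaryMask(mito, 65.0), roi,
                              n_iterations=200, seed=1)
        assert mc.empirical_p == pytest.approx(1 / 201)

    def test_pooled_single_image_equals_monte_carlo_null(self):
        particles, mito, roi = self._setup(seed=5)
        pooled = pooled_enrichment([(particles, mito, roi)], n_iterations=300, seed=9)
        single = monte_carlo_null(
            particles, mito, roi, statistic="fraction_within_nm",
            threshold_nm=100.0, n_iterations=300, seed=9,
        )
        assert pooled.observed == single.observed
        assert pooled.empirical_p == single.empirical_p
        for pa, pb in zip(pooled.bins, single.bins):
            assert pa.expected_fraction == pb.expected_fraction
            assert pa.empirical_p == pb.empirical_p

    def test_pooled_observed_is_weighted_mean_of_images(self):
        p1, mito, roi = self._setup(seed=2)
        p2, _, _ = self._setup(seed=3)
        pooled = pooled_enrichment(
            [(p1, mito, roi), (p2, mito, roi)], n_iterations=100, seed=4
        )
        f1 = summarize_apposition(edge_to_edge_distances(p1, mito))
        f2 = summarize_apposition(edge_to_edge_distances(p2, mito))
        for b, t in zip(pooled.bins, pooled.bins):
            pass
        for b, frA, frB in zip(
            pooled.bins, f1.cumulative_fractions, f2.cumulative_fractions
        ):
            expect = (frA * f1.n_particles + frB * f2.n_particles) / (
                f1.n_particles + f2.n_particles
            )
            assert b.observed_fraction == pytest.approx(expect)

    def test_iteration_floor_enforced(self):
        particles, mito, roi = self._setup()
        with pytest.raises(InputError):
            monte_carlo_null(particles, mito, roi, n_iterations=10, seed=0)


class TestGroupTests:
    @staticmethod
    def _mw_oracle(a, b):
        """Exact two-sided p by enumerating all labelings (no ties)."""
        pooled = np.concatenate([a, b])
        n1 = len(a)
        m = n1 * len(b)
        u_obs = sum(1 for x in a for y in b if x > y)
        us = []
        for comb in itertools.combinations(range(len(pooled)), n1):
            ga = pooled[list(comb)]
            gb = np.delete(pooled, list(comb))
            us.append(sum(1 for x in ga for y in gb if x > y))
        us = np.asarray(us)
        return min(1.0, np.mean(np.abs(us - m / 2) >= abs(u_obs - m / 2)))

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        res = mann_whitney([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.method == "exact"

    def test_matches_enumeration_all_sizes_up_to_10(self):
        rng = np.random.default_rng(7)
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                a, b = vals[:n1], vals[n1:]
                res = mann_whitney(a, b)
                assert res.p_two_sided == pytest.approx(
                    self._mw_oracle(a, b), abs=1e-12
                ), (n1, n2)
                assert 0 <= res.statistic <= n1 * n2

    def test_large_shifted_normals_reject(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(3, 1, 60)
        assert mann_whitney(a, b).p_two_sided < 1e-4

    @staticmethod
    def _fisher_oracle(k1, n1, k2, n2):
        """Two-sided p as the hypergeometric sum of tables at most as probable."""
        total_success = k1 + k2
        n = n1 + n2
        rv = stats.hypergeom(n, total_success, n1)
        kmin = max(0, total_success - n2)
        kmax = min(n1, total_success)
        p_obs = rv.pmf(k1)
        return sum(
            rv.pmf(k)
            for k in range(kmin, kmax + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )

    def test_identical_proportions_p_one(self):
        assert fisher_exact_contact(5, 10, 5, 10).p_two_sided == pytest.approx(1.0)

    def test_matches_hypergeometric_sum(self):
        assert fisher_exact_contact(10, 10, 0, 10).p_two_sided == pytest.approx(
            self._fisher_oracle(10, 10, 0, 10), rel=1e-9
        )
        for k1, n1, k2, n2 in [(3, 5, 1, 5), (2, 4, 4, 6), (0, 3, 3, 7)]:
            assert fisher_exact_contact(k1, n1, k2, n2).p_two_sided == pytest.approx(
                self._fisher_oracle(k1, n1, k2, n2), rel=1e-9
            )

    def test_degenerate_group_is_error(self):
        with pytest.raises(InputError):
            fisher_exact_contact(1, 5, 0, 0)
        with pytest.raises(InputError):
            mann_whitney([], [1.0])
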
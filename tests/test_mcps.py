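"""Circular-variance clustering: mean resultant, fuzzy growth, hard
partitions, series clustering, and the exhaustive-partition oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phasetopo as pt
from _oracle import oracle_partition
from phasetopo.mcps import create_fuzzy_clusters, mean_resultant

angles_strategy = st.lists(
    st.floats(-np.pi, np.pi, allow_nan=False), min_size=1, max_size=12
)


class TestMeanResultant:
    def test_aligned_angles_score_one(self):
        assert mean_resultant([0.7] * 5) == pytest.approx(1.0)

    def test_antipodal_pair_scores_zero(self):
        assert mean_resultant([0.0, np.pi]) == pytest.approx(0.0, abs=1e-12)

    def test_two_thirds_majority(self):
        # {0, 0, pi}: A = 1/3, B = 0
        assert mean_resultant([0.0, 0.0, np.pi]) == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_resultant([])

    @given(angles_strategy)
    def test_bounded_in_unit_interval(self, angles):
        r = mean_resultant(angles)
        assert -1e-12 <= r <= 1 + 1e-12

    @given(angles_strategy, st.floats(-np.pi, np.pi, allow_nan=False))
    def test_rotation_invariant(self, angles, shift):
        a = np.asarray(angles)
        assert mean_resultant(a + shift) == pytest.approx(
            mean_resultant(a), abs=1e-9
        )

    @given(st.floats(-np.pi, np.pi, allow_nan=False))
    def test_singleton_scores_one(self, angle):
        assert mean_resultant([angle]) == pytest.approx(1.0)

    def test_agrees_with_scipy_circular_variance(self, rng):
        from scipy.stats import circvar

        for _ in range(50):
            a = rng.uniform(-np.pi, np.pi, rng.integers(2, 10))
            assert mean_resultant(a) == pytest.approx(1.0 - circvar(a))


class TestFuzzyClusters:
    def test_all_in_phase_collapses_to_one_cluster(self):
        fc = create_fuzzy_clusters(np.full(8, 0.3), r=0.95)
        assert len(fc) == 1
        assert fc[0].members == frozenset(range(8))
        assert fc[0].rbar == pytest.approx(1.0)

    def test_two_rigid_groups_recovered(self):
        # opposite phases: any cross-group addition collapses the resultant
        phases = np.array([0.0] * 4 + [np.pi] * 4)
        fc = create_fuzzy_clusters(phases, r=0.9)
        members = {c.members for c in fc}
        assert members == {frozenset(range(4)), frozenset(range(4, 8))}

    def test_pair_coherence_rate_matches_closed_form(self, rng):
        # two uniform phases cluster iff their circular separation is
        # below 2*acos(r); the separation is uniform on [0, pi], so the
        # clustering probability is exactly 2*acos(r)/pi
        for r in (0.9, 0.99):
            expected = 2 * np.arccos(r) / np.pi
            hits = 0
            n_draws = 4000
            for _ in range(n_draws):
                phases = rng.uniform(-np.pi, np.pi, 2)
                fc = create_fuzzy_clusters(phases, r=r)
                hits += any(len(c.members) == 2 for c in fc)
            se = np.sqrt(expected * (1 - expected) / n_draws)
            assert abs(hits / n_draws - expected) < 5 * se + 1e-3

    def test_strictness_shrinks_largest_cluster(self, rng):
        # per draw, every seed's greedy path is truncated earlier at a
        # stricter threshold, so the largest candidate never grows with r
        for _ in range(300):
            phases = rng.uniform(-np.pi, np.pi, 8)
            sizes = [
                max(len(c.members) for c in create_fuzzy_clusters(phases, r))
                for r in (0.5, 0.9, 0.99)
            ]
            assert sizes[0] >= sizes[1] >= sizes[2]

    def test_threshold_respected(self, rng):
        for _ in range(200):
            phases = rng.uniform(-np.pi, np.pi, 8)
            for fc in create_fuzzy_clusters(phases, r=0.8):
                assert fc.rbar >= 0.8 - 1e-12
                assert fc.rbar == pytest.approx(
                    mean_resultant(phases[list(fc.members)])
                )

    def test_growth_monotone_in_threshold(self, rng):
        # the greedy addition path is threshold-independent, so a stricter
        # threshold can only truncate the cluster grown from a given seed
        for _ in range(100):
            phases = rng.uniform(-np.pi, np.pi, 8)
            for ch in range(8):
                sizes = []
                for r in (0.5, 0.7, 0.9, 0.99):
                    fc = create_fuzzy_clusters(phases, r)
                    sizes.append(
                        max(len(c.members) for c in fc if ch in c.members)
                    )
                assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            create_fuzzy_clusters(np.zeros(4), r=1.5)


class TestHardConversion:
    def test_single_candidate_passes_through(self):
        phases = np.zeros(3)
        fuzzy = [pt.FuzzyCluster(frozenset({0, 1, 2}), 1.0)]
        hp = pt.convert_to_hard(fuzzy, phases, r=0.9)
        assert set(hp.clusters) == {frozenset({0, 1, 2})}

    def test_greedy_order_resolves_overlap(self):
        # {A,B} at 0.99 beats {B,C} at 0.95; C survives as a singleton
        phases = np.array([0.0, 0.1, 0.6])
        fuzzy = [
            pt.FuzzyCluster(frozenset({0, 1}), 0.99),
            pt.FuzzyCluster(frozenset({1, 2}), 0.95),
        ]
        hp = pt.convert_to_hard(fuzzy, phases, r=0.9)
        assert set(hp.clusters) == {frozenset({0, 1}), frozenset({2})}

    def test_partition_valid_on_random_configurations(self, rng):
        for _ in range(2000):
            n = int(rng.integers(2, 9))
            phases = rng.uniform(-np.pi, np.pi, n)
            r = float(rng.uniform(0.3, 0.99))
            hp = pt.cluster_sample(phases, r)
            # disjointness and coverage are enforced by the constructor;
            # recheck the threshold contract on multi-channel clusters
            for c, rb in zip(hp.clusters, hp.rbars):
                if len(c) > 1:
                    assert rb >= r - 1e-12
                    assert rb == pytest.approx(
                        mean_resultant(phases[list(c)])
                    )
            assert frozenset().union(*hp.clusters) == frozenset(range(n))

    def test_singleton_rbar_is_one(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 8)
        hp = pt.cluster_sample(phases, 0.99)
        for c, rb in zip(hp.clusters, hp.rbars):
            if len(c) == 1:
                assert rb == pytest.approx(1.0)


class TestOracleAgreement:
    @pytest.mark.parametrize(
        "sizes,offset",
        [
            ((2, 3), 1.8),
            ((3, 3), np.pi),
            ((2, 4), 2.4),
            ((1, 5), np.pi / 2 + 0.2),
        ],
    )
    def test_matches_exhaustive_search_on_planted_groups(self, sizes, offset):
        # rigid groups (zero internal spread) separated by > pi/2: the
        # exhaustive feasible-partition search and the greedy algorithm
        # must recover exactly the planted blocks
        phases = np.concatenate(
            [np.full(s, i * offset) for i, s in enumerate(sizes)]
        )
        hp = pt.cluster_sample(phases, r=0.9)
        assert set(hp.clusters) == oracle_partition(phases, 0.9)

    def test_oracle_agreement_with_jittered_groups(self, rng):
        # small within-group jitter keeps the planted structure unambiguous
        hits = 0
        for _ in range(50):
            g1 = rng.normal(0.0, 0.05, 3)
            g2 = rng.normal(2.5, 0.05, 3)
            phases = np.concatenate([g1, g2])
            hp = pt.cluster_sample(phases, r=0.9)
            hits += set(hp.clusters) == oracle_partition(phases, 0.9)
        assert hits == 50


class TestClusterSeries:
    def _tensor(self, values, fs=256.0):
        grid = pt.center_frequencies(1.0, 12.0, values.shape[2] + 1)
        grid = pt.FrequencyGrid(grid.fmin, grid.fmax, grid.centers[: values.shape[2]])
        coi = np.zeros((values.shape[1], values.shape[2]), bool)
        return pt.PhaseTensor(values, fs, grid, coi)

    def test_identical_sinusoids_form_full_cluster(self):
        grid = pt.center_frequencies(1.0, 12.0, 12)
        t = np.arange(int(20 * 256)) / 256.0
        row = np.sin(2 * np.pi * 3.0 * t)
        sig = np.tile(row, (5, 1))
        phase = pt.instantaneous_phase(pt.analytic_decompose(sig, grid, 4.0, 256.0))
        cr = pt.cluster_series(phase, 0.9)
        interior = ~phase.coi[:, 0]
        full = pt.mcps.members_to_mask(range(5), 5)
        assert np.all(cr.labels[:, :, interior] == full)

    def test_permutation_equivariance(self, rng):
        values = rng.uniform(-np.pi, np.pi, (6, 40, 2))
        perm = rng.permutation(6)
        cr = pt.cluster_series(self._tensor(values), 0.9)
        cr_p = pt.cluster_series(self._tensor(values[perm]), 0.9)
        for k in range(2):
            for n in range(40):
                orig = {
                    frozenset(np.flatnonzero(cr.labels[k, :, n] == m))
                    for m in np.unique(cr.labels[k, :, n])
                }
                permuted = {
                    frozenset(
                        perm[list(np.flatnonzero(cr_p.labels[k, :, n] == m))]
                    )
                    for m in np.unique(cr_p.labels[k, :, n])
                }
                assert orig == permuted

    def test_series_matches_per_sample_clustering(self, rng):
        values = rng.uniform(-np.pi, np.pi, (7, 25, 3))
        cr = pt.cluster_series(self._tensor(values), 0.85)
        for k in range(3):
            for n in range(25):
                hp = pt.cluster_sample(values[:, n, k], 0.85)
                np.testing.assert_array_equal(cr.labels[k, :, n], hp.labels())

    def test_deterministic(self, rng):
        values = rng.uniform(-np.pi, np.pi, (6, 30, 2))
        a = pt.cluster_series(self._tensor(values), 0.9)
        b = pt.cluster_series(self._tensor(values), 0.9)
        np.testing.assert_array_equal(a.labels, b.labels)
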
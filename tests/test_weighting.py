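import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbmtest.data_model import RegionGenotypes, filter_rare, group_allele_counts
from dbmtest.weighting import (
    adjacent_distances,
    build_position_sequence,
    compute_weights,
    distance_pair,
    frequency_factor,
    nearest_neighbor_distances,
    proximity_factor,
    weighted_counts,
)
from conftest import random_region


class TestNearestNeighborDistances:
    def test_direct_definition(self):
        np.testing.assert_array_equal(
            nearest_neighbor_distances([100, 150, 300]), [50, 50, 150])

    def test_equally_spaced(self):
        np.testing.assert_array_equal(
            nearest_neighbor_distances([0, 10, 20, 30]), [10] * 4)

    def test_matches_all_pairs_brute_force(self, rng):
        pos = np.sort(rng.choice(10_000, size=50, replace=False))
        d = nearest_neighbor_distances(pos)
        brute = [min(abs(p - q) for q in pos if q != p) for p in pos]
        np.testing.assert_array_equal(d, brute)

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError, match="one variant"):
            nearest_neighbor_distances([42])


class TestComputeWeights:
    def test_identical_variants_get_unit_weight(self):
        w = compute_weights([3, 3], 100, [50, 50])
        np.testing.assert_allclose(w, [1.0, 1.0])

    def test_proximity_increases_when_distance_halves(self):
        h = proximity_factor([100, 100, 200])
        h2 = proximity_factor([100, 100, 100])
        assert h2[2] > h[2]

    def test_frequency_factor_decreases_with_count(self):
        f = frequency_factor(np.array([0, 1, 5, 20]), 100)
        assert np.all(np.diff(f) < 0)

    def test_matches_independent_recomputation(self, rng):
        counts = rng.integers(0, 10, size=10)
        n_ref = 50
        nn = rng.integers(1, 1000, size=10)
        w = compute_weights(counts, n_ref, nn)
        # recompute straight from the definition
        q = (counts + 1) / (2 * n_ref + 2)
        f = 1 / np.sqrt(q * (1 - q))
        med = np.median(nn)
        h = med / (nn + med)
        expected = (f * h) / np.mean(f * h)
        np.testing.assert_allclose(w, expected, atol=1e-12)
        assert np.mean(w) == pytest.approx(1.0, abs=1e-12)


class TestWeightedCounts:
    @pytest.mark.parametrize("count,weight,expected", [
        (3, 1.0, 3),
        (1, 0.4, 0),   # variant drops from the sequence
        (5, 0.5, 3),   # half rounds away from zero
    ])
    def test_rounding_rule(self, count, weight, expected):
        wc = weighted_counts(np.array([count]), np.array([0]),
                             np.array([weight]), "case_based")
        assert wc.case_counts[0] == expected


class TestPositionSequence:
    def test_replication(self):
        np.testing.assert_array_equal(
            build_position_sequence([10, 20], [2, 1]), [10, 10, 20])

    def test_all_zero_counts_empty(self):
        assert build_position_sequence([10, 20], [0, 0]).size == 0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_multiset_multiplicity(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(1000, size=6, replace=False))
        counts = rng.integers(0, 5, size=6)
        seq = build_position_sequence(pos, counts)
        for p, c in zip(pos, counts):
            assert np.sum(seq == p) == c
        assert np.all(np.diff(seq) >= 0)


class TestAdjacentDistances:
    def test_zeros_for_repeated_positions(self):
        np.testing.assert_array_equal(
            adjacent_distances([10, 10, 20, 50]), [0, 10, 30])

    def test_degenerate_singleton(self):
        assert adjacent_distances([5]).size == 0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_prefix_sum_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        seq = np.sort(rng.integers(0, 1000, size=8))
        d = adjacent_distances(seq)
        np.testing.assert_array_equal(np.concatenate([[seq[0]],
                                                      seq[0] + np.cumsum(d)]),
                                      seq)


class TestDistancePair:
    def test_identical_groups_give_identical_vectors(self):
        row = [1, 0, 2, 1]
        region = RegionGenotypes(
            positions=[10, 40, 60, 200],
            genotypes=np.array([row, row, row, row], dtype=float),
            phenotype=[1, 1, 0, 0],
        )
        rare = filter_rare(region, 0.5)
        for scheme in ("case_based", "control_based"):
            pair = distance_pair(region, rare, scheme)
            np.testing.assert_array_equal(pair.case_distances,
                                          pair.control_distances)

    def test_pipeline_equals_manual_composition(self, rng):
        region = random_region(rng, n_subjects=12, n_variants=6)
        rare = filter_rare(region, 0.5)
        pair = distance_pair(region, rare, "case_based")

        ca, cu, _, _ = group_allele_counts(region, rare)
        pos = region.positions[rare.indices]
        nn = nearest_neighbor_distances(pos)
        w = compute_weights(ca, region.n_cases, nn)
        wc = weighted_counts(ca, cu, w, "case_based")
        np.testing.assert_array_equal(
            pair.case_distances,
            adjacent_distances(build_position_sequence(pos, wc.case_counts)))
        np.testing.assert_array_equal(
            pair.control_distances,
            adjacent_distances(build_position_sequence(pos, wc.control_counts)))

    def test_label_swap_swaps_schemes(self, rng):
        region = random_region(rng, n_subjects=10, n_variants=5)
        rare = filter_rare(region, 0.5)
        swapped = 1 - region.phenotype
        a = distance_pair(region, rare, "case_based")
        b = distance_pair(region, rare, "control_based", phenotype=swapped)
        np.testing.assert_array_equal(a.case_distances, b.control_distances)
        np.testing.assert_array_equal(a.control_distances, b.case_distances)

    def _no_dropout(self, region, rare):
        """True when no variant with a positive raw count rounds to zero
        under either scheme's weights."""
        ca, cu, _, _ = group_allele_counts(region, rare)
        pos = region.positions[rare.indices]
        nn = nearest_neighbor_distances(pos)
        for ref, n_ref in ((ca, region.n_cases), (cu, region.n_controls)):
            w = compute_weights(ref, n_ref, nn)
            wc = weighted_counts(ca, cu, w, "check")
            if (np.any((wc.case_counts == 0) & (ca > 0))
                    or np.any((wc.control_counts == 0) & (cu > 0))):
                return False
        return True

    def test_schemes_share_distinct_nonzero_distances_when_no_dropout(self, rng):
        # weighting changes only multiplicities (skewness); with no count
        # rounding to zero, the set of distinct non-zero distances is the
        # same under both schemes
        checked = 0
        for _ in range(20):
            region = random_region(rng, n_subjects=30, n_variants=8)
            region.genotypes[:] = np.clip(region.genotypes + 1, 0, 2)
            rare = filter_rare(region, 0.5)
            if not self._no_dropout(region, rare):
                continue
            a = distance_pair(region, rare, "case_based")
            b = distance_pair(region, rare, "control_based")
            for da, db in ((a.case_distances, b.case_distances),
                           (a.control_distances, b.control_distances)):
                assert set(da[da > 0].tolist()) == set(db[db > 0].tolist())
            checked += 1
        assert checked > 0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_zero_inflation_monotonicity(self, seed):
        # bumping one count adds a zero distance or splits one gap in two
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(1000, size=5, replace=False))
        counts = rng.integers(0, 4, size=5)
        j = int(rng.integers(5))
        d0 = adjacent_distances(build_position_sequence(pos, counts))
        counts2 = counts.copy()
        counts2[j] += 1
        d1 = adjacent_distances(build_position_sequence(pos, counts2))
        assert d1.size == d0.size + 1 or d0.size == 0
        assert d1.sum() >= d0.sum()  # total distance = occupied span, grows
        if counts[j] > 0 and d0.size > 0:
            # position already present: exactly one extra zero distance
            assert np.sum(d1 == 0) == np.sum(d0 == 0) + 1
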
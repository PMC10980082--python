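"""Sampling schemes, mutation placement, and minor-allele coding."""

import msprime
import numpy as np
import pytest
from scipy import stats

from mapnn.genotypes import (
    SampleSet,
    minor_allele_code,
    place_mutations,
    recapitate,
    sample_fixed,
    sample_grid,
    sample_uniform,
    simulate_genotypes,
)
from mapnn.maps import DemographicMap
from mapnn.sim import SimParams, SimResult


def fake_sim(x, y, width=10):
    """A SimResult shell holding only locations (sampling needs no genetics)."""
    w = width
    dmap = DemographicMap(
        np.ones((w, w)), np.ones((w, w)), np.ones((w, w), dtype=bool)
    )
    x = np.asarray(x, dtype=float)
    return SimResult(
        x=x, y=np.asarray(y, dtype=float), extinct=False, n_generations_run=1,
        census=np.array([x.size]), births=np.array([0]),
        params=SimParams(n_generations=1, burn_in=0), dmap=dmap, seed=0,
    )


class TestSampleUniform:
    def test_whole_population_when_n_equals_size(self):
        sim = fake_sim([1, 2, 3], [1, 2, 3])
        ss = sample_uniform(sim, 3, np.random.default_rng(0))
        assert sorted(ss.indices.tolist()) == [0, 1, 2]

    def test_inclusion_frequency_uniform(self):
        sim = fake_sim(np.arange(20.0), np.arange(20.0) % 10)
        counts = np.zeros(20)
        reps = 3000
        rng = np.random.default_rng(1)
        for _ in range(reps):
            counts[sample_uniform(sim, 5, rng).indices] += 1
        freq = counts / reps
        np.testing.assert_allclose(freq, 0.25, atol=0.03)

    def test_insufficient_population_raises(self):
        with pytest.raises(ValueError):
            sample_uniform(fake_sim([1], [1]), 2, np.random.default_rng(0))


class TestSampleGrid:
    def test_one_per_cell_deterministic(self):
        # exactly one individual in each cell of a 2x2 grid on a 10-wide map
        sim = fake_sim([2, 7, 2, 7], [2, 2, 7, 7])
        ss = sample_grid(sim, 1, 2, np.random.default_rng(0))
        assert sorted(ss.indices.tolist()) == [0, 1, 2, 3]
        assert ss.n == 4

    def test_count_is_per_cell_times_cells(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 400)
        y = rng.uniform(0, 10, 400)
        ss = sample_grid(fake_sim(x, y), 4, 5, rng)
        assert ss.n == 100
        # exactly four per cell
        cx = (ss.locations[:, 0] // 2).astype(int)
        cy = (ss.locations[:, 1] // 2).astype(int)
        counts = np.zeros((5, 5), int)
        np.add.at(counts, (cy, cx), 1)
        assert np.all(counts == 4)

    def test_empty_cell_error_names_cell(self):
        sim = fake_sim([1, 1, 1], [1, 1, 1])  # everything in one corner
        with pytest.raises(ValueError, match=r"\(1, 0\)|\(0, 1\)"):
            sample_grid(sim, 1, 2, np.random.default_rng(0))


class TestSampleFixed:
    def test_individual_exactly_at_target(self):
        sim = fake_sim([3.0, 8.0], [3.0, 8.0])
        ss = sample_fixed(sim, [(3.0, 3.0)], np.random.default_rng(0))
        assert ss.indices.tolist() == [0]

    def test_radius_doubles_until_found(self):
        # nearest individual at 0.05 * width: initial 0.02w misses, 0.04w
        # misses, 0.08w catches it
        sim = fake_sim([5.5], [5.0], width=10)
        ss = sample_fixed(sim, [(5.0, 5.0)], np.random.default_rng(0))
        assert ss.indices.tolist() == [0]

    def test_no_duplicate_individuals(self):
        sim = fake_sim([2.0, 2.1, 8.0], [2.0, 2.1, 8.0])
        ss = sample_fixed(sim, [(2.0, 2.0), (2.1, 2.1)], np.random.default_rng(3))
        assert len(set(ss.indices.tolist())) == 2
        assert set(ss.indices.tolist()) <= {0, 1}

    def test_more_targets_than_individuals_raises(self):
        sim = fake_sim([1.0], [1.0])
        with pytest.raises(ValueError):
            sample_fixed(sim, [(1, 1), (2, 2)], np.random.default_rng(0))


class TestMinorAlleleCodeProperties:
    """Invariants of minor-allele coding on arbitrary polymorphic matrices."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @given(
        hnp.arrays(
            np.int8,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=12),
            elements=st.integers(0, 2),
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_maf_bounded_and_idempotent(self, raw):
        n = raw.shape[0]
        polymorphic = ~np.isin(raw.sum(axis=0), [0, 2 * n])
        raw = raw[:, polymorphic]
        if raw.shape[1] == 0:
            return
        coded = minor_allele_code(raw)
        maf = coded.values.sum(axis=0) / (2 * n)
        assert np.all(maf > 0) and np.all(maf <= 0.5)
        again = minor_allele_code(coded.values)
        np.testing.assert_array_equal(coded.values, again.values)


class TestMinorAlleleCode:
    def test_majority_column_flipped(self):
        raw = np.array([[2, 2], [2, 0], [2, 0], [1, 0], [0, 0]])
        # col 0 alt freq 0.7 -> flipped; col 1 alt freq 0.2 -> kept
        coded = minor_allele_code(raw)
        np.testing.assert_array_equal(coded.values[:, 0], [0, 0, 0, 1, 2])
        np.testing.assert_array_equal(coded.values[:, 1], [2, 0, 0, 0, 0])
        assert np.all(coded.values.sum(axis=0) / (2 * 5) <= 0.5)

    def test_exact_tie_keeps_derived_allele(self):
        raw = np.array([[2], [0]])  # frequency exactly 0.5
        coded = minor_allele_code(raw)
        np.testing.assert_array_equal(coded.values[:, 0], [2, 0])

    def test_idempotent(self, rng):
        raw = rng.integers(0, 3, size=(10, 20))
        keep = ~np.isin(raw.sum(axis=0), [0, 20])
        raw = raw[:, keep]
        once = minor_allele_code(raw)
        twice = minor_allele_code(once.values)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            minor_allele_code(np.array([[0, 1], [0, 1]]))

    def test_non_biallelic_rejected(self):
        with pytest.raises(ValueError):
            minor_allele_code(np.array([[3], [1]]))


def _panmictic_ts(n_ind=10, Ne=200, seed=7):
    return msprime.sim_ancestry(
        samples=n_ind, population_size=Ne, sequence_length=5e6,
        recombination_rate=1e-8, random_seed=seed,
    )


class TestPlaceMutations:
    def test_exact_snp_count_and_maf(self):
        ts = _panmictic_ts()
        for seed in (0, 1):
            gm = place_mutations(ts, 80, np.random.default_rng(seed))
            assert gm.values.shape == (10, 80)
            assert np.all(np.diff(gm.positions) >= 0)
            maf = gm.values.sum(axis=0) / 20
            assert np.all(maf > 0) and np.all(maf <= 0.5)

    def test_phased_mode_haplotypes_sum_to_diploid(self):
        ts = _panmictic_ts(seed=9)
        gm = place_mutations(ts, 50, np.random.default_rng(2), phased=True)
        assert gm.haplotypes.shape == (20, 50)
        hap_sum = gm.haplotypes.reshape(10, 2, 50).sum(axis=1)
        flipped = np.where(
            hap_sum.sum(axis=0) / 20 > 0.5, 2 - hap_sum, hap_sum
        )
        np.testing.assert_array_equal(gm.values, flipped)

    def test_folded_sfs_matches_neutral_expectation(self):
        # coalescent oracle: folded SFS eta_i ~ 1/i + 1/(2n-i) in
        # expectation.  A single genealogy deviates wildly (marginal trees
        # are correlated), so the check averages over replicate histories
        # and compares each class within its Monte-Carlo error.
        n2 = 16
        reps = []
        for seed in range(1, 25):
            ts = _panmictic_ts(n_ind=8, Ne=500, seed=seed)
            gm = place_mutations(ts, 400, np.random.default_rng(seed))
            counts = gm.values.sum(axis=0)
            hist = np.bincount(counts, minlength=n2 // 2 + 1)[1:]
            reps.append(hist / hist.sum())
        reps = np.array(reps)
        expected = np.array(
            [1 / i + (1 / (n2 - i) if i != n2 - i else 0) for i in range(1, n2 // 2 + 1)]
        )
        expected /= expected.sum()
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        assert np.all(np.abs(mean - expected) < 4 * se + 0.01)

    def test_empty_tree_sequence_rejected(self):
        import tskit

        tables = tskit.TableCollection(sequence_length=100)
        with pytest.raises(ValueError):
            place_mutations(tables.tree_sequence(), 5, np.random.default_rng(0))


class TestEndToEndGenotypes:
    def test_pipeline_shapes_and_polymorphism(self, tiny_sim):
        rng = np.random.default_rng(0)
        ss = sample_uniform(tiny_sim, 8, rng)
        gm = simulate_genotypes(tiny_sim, ss, 40, 123)
        assert gm.values.shape == (8, 40)
        freq = gm.values.sum(axis=0) / 16
        assert np.all(freq > 0) and np.all(freq <= 0.5)

    def test_pairwise_diversity_matches_coalescent_expectation(self):
        # a single spatial generation on a tiny dense habitat is effectively
        # random mating, so diversity should track theta = 4 Ne mu
        from mapnn.maps import DemographicMap
        from mapnn.sim import SimParams, simulate

        w = 4
        dmap = DemographicMap(
            np.full((w, w), 3.0), np.full((w, w), 2.0), np.ones((w, w), bool)
        )
        Ne = 40.0
        params = SimParams(
            n_generations=1, burn_in=0, epochs=((Ne, None),),
            genome=((2e7, 1e-8),),
        )
        sim = simulate(dmap, params, seed=6, record_realized=False,
                       record_genealogy=True)
        ss = sample_uniform(sim, 10, np.random.default_rng(0))
        ts = recapitate(sim, ss, seed=11)
        mu = 2e-8
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=5)
        pi = mts.diversity(mode="site")
        theta = 4 * Ne * mu
        # recombination across 20 Mb keeps the variance modest
        assert pi == pytest.approx(theta, rel=0.35)
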
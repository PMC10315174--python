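"""Summary statistics: fitness moments, fixations, heterozygosity, DFE."""

import math

import numpy as np
import pytest

from canevo import (
    Environment,
    GPMap,
    Population,
    SimulationRecord,
    count_fixations,
    fixation_rate,
    heterozygosity,
    mean_fitness,
    rlocus_frequencies,
    selection_coefficients,
)
from canevo.gpmap import InitParams, init_map, random_founder


def population_with_classes(counts, flip_sites, L=4, K=2):
    """Founder-rooted population whose extra classes flip the given sites."""
    m = GPMap(T=np.zeros((K, L), dtype=np.int8), h=np.full(K, 0.5))
    env = Environment(b=np.zeros(K, dtype=np.uint8), kind="opt")
    pop = Population(m, env, np.zeros(L, dtype=np.uint8), int(sum(counts)))
    finals = [0]
    for sites in flip_sites:
        ci = 0
        for s in sites:
            ci = pop._spawn(ci, flip_site=s)  # intermediates get count 0
        finals.append(ci)
    pop._flush()
    full = np.zeros(pop.n_classes, dtype=np.int64)
    full[finals] = counts
    pop.counts = full
    pop._compact()
    return pop


class TestMeanFitness:
    def test_homogeneous_optimal(self, tiny_fixture):
        gpmap, founder, envs = tiny_fixture
        pop = Population(gpmap, envs[0], founder, 12)
        assert mean_fitness(pop) == (1.0, 0.0)

    def test_two_equal_classes(self):
        pop = population_with_classes([5, 5], [[0]])
        pop.w = np.array([1.0, 0.0])
        assert mean_fitness(pop) == (0.5, 0.25)

    def test_weighted_three_class_moments(self):
        pop = population_with_classes([2, 3, 5], [[0], [1]])
        pop.w = np.array([1.0, 0.8, 0.5])
        mw, vw = mean_fitness(pop)
        expected_mean = (2 * 1.0 + 3 * 0.8 + 5 * 0.5) / 10
        expected_var = (2 * (1.0 - expected_mean) ** 2
                        + 3 * (0.8 - expected_mean) ** 2
                        + 5 * (0.5 - expected_mean) ** 2) / 10
        assert mw == pytest.approx(expected_mean)
        assert vw == pytest.approx(expected_var)


class TestFixations:
    def test_homogeneous_founder_population_has_none(self, tiny_fixture):
        gpmap, founder, envs = tiny_fixture
        pop = Population(gpmap, envs[0], founder, 10)
        pop.update_fixations()
        assert count_fixations(pop) == 0

    def test_episode_bookkeeping_counts_refixation(self):
        """fix -> revert -> re-fix at one site scores two episodes."""
        pop = population_with_classes([9, 1], [[0]])
        pop.counts = np.array([0, 10], dtype=np.int64)   # site 0 fixed
        pop.update_fixations()
        assert count_fixations(pop) == 1
        pop.counts = np.array([10, 0], dtype=np.int64)   # reverted
        pop.update_fixations()
        assert count_fixations(pop) == 1
        pop.counts = np.array([0, 10], dtype=np.int64)   # fixed again
        pop.update_fixations()
        assert count_fixations(pop) == 2
        assert [site for _, site in pop.fix_events] == [0, 0]

    def test_partial_sweep_is_not_a_fixation(self):
        pop = population_with_classes([1, 9], [[0]])
        pop.update_fixations()
        assert count_fixations(pop) == 0


class TestFixationRate:
    def _record(self, events, span):
        rec = SimulationRecord()
        rec.generations = [0, span]
        rec.fixation_events = events
        return rec

    def test_zero_events(self):
        assert fixation_rate(self._record([], 2_000_000)) == (0.0, 0.0)

    def test_per_thousand_generation_units(self):
        events = [(g, 0) for g in (10, 500_000, 999_999, 1_500_000, 1_800_000)]
        early, late = fixation_rate(self._record(events, 2_000_000))
        assert early == pytest.approx(3 / 1000)
        assert late == pytest.approx(2 / 1000)

    def test_windows_must_fit_record(self):
        with pytest.raises(ValueError):
            fixation_rate(self._record([], 500_000))


class TestHeterozygosity:
    def test_homogeneous_is_zero(self, tiny_fixture):
        gpmap, founder, envs = tiny_fixture
        assert heterozygosity(Population(gpmap, envs[0], founder, 10)) == 0.0

    def test_single_half_frequency_site(self):
        pop = population_with_classes([5, 5], [[0]], L=4)
        assert heterozygosity(pop) == pytest.approx(0.5 / 4)

    def test_matches_pairwise_difference_oracle(self):
        pop = population_with_classes([3, 4, 2, 1], [[0], [0, 1], [2, 3]], L=4)
        # E over ordered pairs (with replacement) of the per-site mismatch
        V, c = pop._V, pop.counts
        N = c.sum()
        mismatch = 0.0
        for i in range(len(c)):
            for j in range(len(c)):
                mismatch += c[i] * c[j] * np.mean(V[i] != V[j])
        assert heterozygosity(pop) == pytest.approx(mismatch / N**2)

    def test_bounded_by_half(self):
        pop = population_with_classes([5, 5], [[0, 1, 2, 3]], L=4)
        assert 0.0 <= heterozygosity(pop) <= 0.5


class TestSelectionCoefficients:
    def test_silent_map_gives_zero(self, rng):
        pop = population_with_classes([10], [], L=6, K=3)  # T is all zero
        s = selection_coefficients(pop, 50, rng)
        assert np.all(s == 0.0)

    def test_breaking_one_of_two_traits(self, rng):
        # flipping the single gene turns trait 0 ON while the optimum wants
        # it OFF: W drops from 1 to 0.5, so s = -0.5 for every draw
        m = GPMap(T=np.array([[1], [0]], dtype=np.int8), h=np.array([0.5, -0.5]))
        env = Environment(b=np.array([0, 1], dtype=np.uint8), kind="opt")
        pop = Population(m, env, np.zeros(1, dtype=np.uint8), 10)
        s = selection_coefficients(pop, 20, rng)
        assert np.all(s == pytest.approx(-0.5))

    def test_all_deleterious_at_optimum(self):
        """At W=1 under the optimal environment every phenotype change can
        only lower fitness, so all sampled coefficients are <= 0."""
        rng = np.random.default_rng(31)
        founder = random_founder(200, 0.5, rng)
        m = init_map(InitParams(K=10, L=200, gamma=10.0), founder, rng)
        env = Environment(b=(m.gamma * m.scores(founder) - m.h > 0).astype(np.uint8),
                          kind="opt")
        pop = Population(m, env, founder, 50)
        s = selection_coefficients(pop, 500, rng)
        assert np.all(s <= 0.0)
        assert np.any(s < 0.0)

    def test_changing_fraction_matches_exhaustive_probability(self):
        """The fraction of phenotype-changing draws agrees (binomially) with
        the exact per-site probability computed by exhaustive flips."""
        rng = np.random.default_rng(77)
        founder = random_founder(300, 0.5, rng)
        m = init_map(InitParams(K=100, L=300, gamma=1.0), founder, rng)
        env = Environment(b=(m.scores(founder) - m.h > 0).astype(np.uint8),
                          kind="opt")
        pop = Population(m, env, founder, 20)
        # exact probability that a uniform flip changes >= 1 trait
        y0 = m.scores(founder) - m.h
        delta = m.T * (1.0 - 2.0 * founder)
        changes = ((y0[:, None] + delta > 0) != (y0 > 0)[:, None]).any(axis=0)
        p_exact = changes.mean()
        assert p_exact > 0
        n = 2000
        s = selection_coefficients(pop, n, rng)
        frac = np.mean(s != 0.0)
        assert abs(frac - p_exact) < 3 * math.sqrt(p_exact * (1 - p_exact) / n)


class TestRlocusFrequencies:
    def test_requires_evolving_mode(self, tiny_fixture):
        gpmap, founder, envs = tiny_fixture
        with pytest.raises(ValueError):
            rlocus_frequencies(Population(gpmap, envs[0], founder, 10))

    def test_matches_direct_count(self):
        m = GPMap(T=np.zeros((2, 3), dtype=np.int8), h=np.full(2, 0.5),
                  mode="alpha", anchor_sums=np.zeros(2))
        env = Environment(b=np.zeros(2, dtype=np.uint8), kind="opt")
        counts = np.array([4, 0, 0, 6, 0, 0, 0, 10], dtype=np.int64)
        pop = Population(m, env, np.zeros(3, dtype=np.uint8), 20,
                         rloc_counts=counts)
        freqs = rlocus_frequencies(pop)
        np.testing.assert_allclose(freqs, counts / 20)
        assert freqs.sum() == pytest.approx(1.0)

    def test_fixed_locus_is_unit_mass(self):
        m = GPMap(T=np.zeros((2, 3), dtype=np.int8), h=np.full(2, 0.5),
                  mode="alpha", anchor_sums=np.zeros(2))
        env = Environment(b=np.zeros(2, dtype=np.uint8), kind="opt")
        counts = np.zeros(8, dtype=np.int64)
        counts[3] = 15
        pop = Population(m, env, np.zeros(3, dtype=np.uint8), 15,
                         rloc_counts=counts)
        assert rlocus_frequencies(pop)[3] == 1.0
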
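"""Genotype sampling, phenotype binarization, IG fitness, and GP evolution."""

import numpy as np
import pytest

import helpers
from conftest import tree_from_sexp
from epiforest.errors import (
    DegenerateModelError,
    InvalidArgumentError,
)
from epiforest.infotheory import interaction_network
from epiforest.simulator import (
    IGFitnessEvaluator,
    SimulationConfig,
    binarize_phenotype,
    evolve_dataset,
    generate_replicates,
    replicate_seed_for,
    sample_genotypes,
)

FAST_GP = dict(gp_population_size=30, generations=10)


class TestSampleGenotypes:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_samples=6, n_features=2)
        a = sample_genotypes(cfg, np.random.default_rng(5)).genotypes
        b = sample_genotypes(cfg, np.random.default_rng(5)).genotypes
        np.testing.assert_array_equal(a, b)

    def test_uniform_frequencies_within_binomial_bounds(self, rng):
        n = 30000
        cfg = SimulationConfig(n_samples=n, n_features=3)
        g = sample_genotypes(cfg, rng).genotypes
        p, sigma = 1 / 3, np.sqrt((1 / 3) * (2 / 3) / (n * 3))
        for v in (0, 1, 2):
            freq = (g == v).mean()
            assert abs(freq - p) < 3 * sigma

    def test_single_feature_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(n_features=1)


class TestBinarizePhenotype:
    def test_quantile_threshold(self, rng):
        y = binarize_phenotype(np.array([0.0, 1.0, 2.0, 3.0]), 0.5, rng)
        np.testing.assert_array_equal(y, [0, 0, 1, 1])

    def test_constant_raw_is_degenerate(self, rng):
        with pytest.raises(DegenerateModelError):
            binarize_phenotype(np.full(4, 5.0), 0.25, rng)

    def test_exact_case_count_with_distinct_values(self, rng):
        y = binarize_phenotype(np.arange(8.0), 0.25, rng)
        assert y.sum() == 2
        assert set(np.flatnonzero(y)) == {6, 7}

    def test_exact_case_count_with_heavy_ties(self, rng):
        raw = np.array([0.0] * 50 + [1.0] * 50)
        for cf in (0.25, 0.5, 0.75):
            y = binarize_phenotype(raw, cf, rng)
            assert y.sum() == round(100 * cf)

    def test_ties_never_steal_from_strictly_above(self, rng):
        raw = np.array([0.0] * 7 + [1.0] * 3)
        y = binarize_phenotype(raw, 0.5, rng)
        assert y[7:].all()  # strictly-above-threshold samples are cases
        assert y.sum() == 5


class TestIGFitness:
    def test_xor_tree_dominates_its_pair(self, xor_tree, rng):
        cfg = SimulationConfig(n_samples=4000, case_fraction=0.5, ig_order=2)
        g = sample_genotypes(cfg, rng)
        ev = IGFitnessEvaluator(g, cfg)
        _, size = ev(xor_tree, rng)
        assert size == xor_tree.size
        # the aggregate is dominated by the planted pair's IG2
        y = ev.phenotype_for_tree(xor_tree, np.random.default_rng(0))
        ig_obj = ev.objective_for_phenotype(y)
        ds = helpers.xor_dataset(10, 5, (0, 1), rng)  # container reuse
        ds.genotypes, ds.phenotype = g.genotypes, y
        net = interaction_network(ds)
        top_pair_ig = max(net.pairwise_ig.values())
        assert ig_obj == pytest.approx(sum(net.pairwise_ig.values()), abs=1e-9)
        assert top_pair_ig / ig_obj > 0.8

    def test_constant_tree_gets_worst_fitness(self, rng):
        cfg = SimulationConfig(n_samples=100)
        g = sample_genotypes(cfg, rng)
        ev = IGFitnessEvaluator(g, cfg)
        const_tree = tree_from_sexp([("op", "SUB"), ("const", 2), ("const", 2)])
        ig_obj, _ = ev(const_tree, rng)
        assert ig_obj == -np.inf

    def test_fitness_deterministic_for_same_tree(self, xor_tree, rng):
        cfg = SimulationConfig(n_samples=500)
        g = sample_genotypes(cfg, rng)
        ev = IGFitnessEvaluator(g, cfg)
        assert ev(xor_tree, rng) == ev(xor_tree, rng)

    def test_wide_matrix_fallback_agrees_with_tensor(self, xor_tree, rng):
        cfg = SimulationConfig(n_samples=400, n_features=5)
        g = sample_genotypes(cfg, rng)
        ev = IGFitnessEvaluator(g, cfg)
        y = ev.phenotype_for_tree(xor_tree, np.random.default_rng(1))
        direct = ev.objective_for_phenotype(y)
        ev._tensor_path = False  # force the per-combination path
        assert ev.objective_for_phenotype(y) == pytest.approx(direct, abs=1e-10)


class TestEvolveDataset:
    def test_bit_identical_on_rerun(self):
        cfg = SimulationConfig(n_samples=300, seed=11, **FAST_GP)
        a, b = evolve_dataset(cfg), evolve_dataset(cfg)
        np.testing.assert_array_equal(a.dataset.genotypes, b.dataset.genotypes)
        np.testing.assert_array_equal(a.dataset.phenotype, b.dataset.phenotype)
        assert a.tree.signature() == b.tree.signature()
        assert a.fitness_at_end == b.fitness_at_end

    def test_best_fitness_monotone_over_generations(self):
        cfg = SimulationConfig(n_samples=300, seed=4, **FAST_GP)
        rep = evolve_dataset(cfg)
        best = [h["best_ig"] for h in rep.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert rep.history[-1]["best_ig"] >= rep.history[0]["best_ig"]

    def test_selection_pressure_raises_mean_fitness(self):
        gains = []
        for seed in range(5):
            cfg = SimulationConfig(n_samples=300, seed=seed, **FAST_GP)
            rep = evolve_dataset(cfg)
            gains.append(rep.history[-1]["mean_ig"] - rep.history[0]["mean_ig"])
        assert np.mean(gains) > 0

    def test_exact_case_count_contract(self):
        cfg = SimulationConfig(
            n_samples=1000, case_fraction=0.25, seed=9, **FAST_GP
        )
        rep = evolve_dataset(cfg)
        assert rep.dataset.case_count == 250

    def test_emitted_dataset_is_reproducible_from_seed_and_tree(self):
        cfg = SimulationConfig(n_samples=400, seed=21, **FAST_GP)
        rep = evolve_dataset(cfg)
        # re-create genotypes and phenotype from the stored triple alone
        from epiforest.simulator import _seed_streams

        rng_geno, rng_bin, _ = _seed_streams(rep.replicate_seed)
        g2 = sample_genotypes(cfg, rng_geno)
        ev = IGFitnessEvaluator(g2, cfg)
        y2 = ev.phenotype_for_tree(rep.tree, rng_bin)
        np.testing.assert_array_equal(g2.genotypes, rep.dataset.genotypes)
        np.testing.assert_array_equal(y2, rep.dataset.phenotype)


class TestGenerateReplicates:
    def test_distinct_and_stable_across_reruns(self):
        cfg = SimulationConfig(n_samples=200, seed=3, **FAST_GP)
        reps1 = generate_replicates(cfg, 3)
        reps2 = generate_replicates(cfg, 3)
        assert len(reps1) == 3
        seeds = {r.replicate_seed for r in reps1}
        assert len(seeds) == 3
        for r1, r2 in zip(reps1, reps2):
            np.testing.assert_array_equal(r1.dataset.phenotype, r2.dataset.phenotype)

    def test_seed_derivation_is_stable(self):
        assert replicate_seed_for(7, 0) == replicate_seed_for(7, 0)
        assert replicate_seed_for(7, 0) != replicate_seed_for(7, 1)
        assert 0 <= replicate_seed_for(7, 123) < 2**31

    def test_zero_replicates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_replicates(SimulationConfig(), 0)


def test_evolved_datasets_carry_positive_pairwise_ig():
    """The fitness is achievable: the strongest pairwise IG of emitted
    datasets is strictly positive in nearly all replicates."""
    cfg = SimulationConfig(n_samples=500, seed=17, ig_order=2, **FAST_GP)
    reps = generate_replicates(cfg, 10)
    positive = 0
    for rep in reps:
        net = interaction_network(rep.dataset)
        positive += max(net.pairwise_ig.values()) > 0
    assert positive >= 9
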
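import json

import numpy as np
import pytest

from dotslab.gp import (
    ERC_RANGE,
    GPConfig,
    GPResult,
    crossover,
    desk_gp_config,
    evaluate_tree,
    evolve,
    fitness,
    from_sexpr,
    identity_tree,
    mutate,
    random_tree,
    refine_predictions,
    to_sexpr,
    tournament_select,
    tree_depth,
)

CFG = desk_gp_config()


def _erc_values(tree, out=None):
    if out is None:
        out = []
    if isinstance(tree, (int, np.integer)):
        out.append(int(tree))
    elif isinstance(tree, tuple):
        for c in tree[1:]:
            _erc_values(c, out)
    return out


def _n_differing_subtrees(a, b):
    """Count maximal differing subtrees between two trees."""
    if a == b:
        return 0
    if isinstance(a, tuple) and isinstance(b, tuple) and a[0] == b[0] and len(a) == len(b):
        return sum(_n_differing_subtrees(x, y) for x, y in zip(a[1:], b[1:]))
    return 1


class TestRandomTree:
    def test_depth_and_erc_bounds_over_many_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(5000):
            t = random_tree(CFG, rng)
            assert 2 <= tree_depth(t) <= 6
            assert all(ERC_RANGE[0] <= v <= ERC_RANGE[1] for v in _erc_values(t))

    def test_same_rng_state_gives_identical_tree(self):
        assert random_tree(CFG, np.random.default_rng(9)) == random_tree(
            CFG, np.random.default_rng(9)
        )


class TestEvaluate:
    def test_quadratic_example(self):
        # x^2 + (-5x) at x = 2 -> 4 - 10 = -6
        t = ("add", ("multiply", "x", "x"), ("negate", ("multiply", "x", 5)))
        assert evaluate_tree(t, 2.0) == -6.0

    def test_identity_equivalent_tree(self):
        vals = np.linspace(-3, 3, 11)
        np.testing.assert_array_equal(evaluate_tree(identity_tree(), vals), vals)

    def test_protected_division(self):
        assert evaluate_tree(("divide", 1, 0), 0.0) == 1.0
        assert evaluate_tree(("divide", "x", "x"), 0.0) == 1.0  # |den| < 1e-6
        assert evaluate_tree(("divide", 4, 2), 0.0) == 2.0

    def test_malformed_tree_rejected(self):
        with pytest.raises(ValueError):
            evaluate_tree(("add", "x"), 1.0)
        with pytest.raises(ValueError):
            evaluate_tree(("exp", "x", "x"), 1.0)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            t = random_tree(CFG, rng)
            assert from_sexpr(json.loads(json.dumps(to_sexpr(t)))) == t

    def test_sexpr_matches_documented_form(self):
        t = ("add", ("multiply", "x", "x"), ("negate", ("multiply", "x", 5)))
        assert to_sexpr(t) == ["add", ["multiply", "x", "x"], ["negate", ["multiply", "x", 5]]]


class TestFitness:
    def test_identity_on_perfect_predictions(self):
        v = np.linspace(0, 1, 50)
        assert fitness(identity_tree(), v, v, 1.0, 0) == 0.0

    def test_unit_residuals(self):
        zeros = ("multiply", "x", 0)
        preds = np.linspace(0, 1, 40)
        truths = np.ones(40)
        assert fitness(zeros, preds, truths, 1.0, 0) == pytest.approx(1.0)

    def test_nonfinite_output_maps_to_inf_sentinel(self):
        t = ("multiply", "x", "x")
        assert fitness(t, np.array([1e300]), np.array([0.0]), 1.0, 0) == float("inf")

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            fitness(identity_tree(), np.zeros(3), np.zeros(4), 0.5, 0)


class TestTournament:
    def test_population_of_one(self):
        assert tournament_select(["a"], [1.0], 4, np.random.default_rng(0)) == "a"

    def test_full_coverage_returns_global_best(self):
        pop = ["t0", "t1", "t2", "t3"]
        fits = [3.0, 1.0, 2.0, 4.0]
        found = False
        for seed in range(200):
            probe = np.random.default_rng(seed).integers(0, 4, size=4)
            if len(set(probe.tolist())) == 4:  # this seed draws all individuals
                winner = tournament_select(pop, fits, 4, np.random.default_rng(seed))
                assert winner == "t1"
                found = True
        assert found

    def test_selection_pressure(self):
        rng = np.random.default_rng(1)
        fits = rng.uniform(0, 1, 200).tolist()
        pop = list(range(200))
        winners = [
            fits[tournament_select(pop, fits, 4, np.random.default_rng(s))]
            for s in range(1000)
        ]
        assert np.mean(winners) <= np.mean(fits)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            tournament_select([], [], 4, np.random.default_rng(0))


class TestOperatorsClosure:
    def test_crossover_respects_depth_and_structure(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            a = random_tree(CFG, rng)
            b = random_tree(CFG, rng)
            c1, c2 = crossover(a, b, rng, CFG)
            for c in (c1, c2):
                assert 2 <= tree_depth(c) <= 6
                assert from_sexpr(to_sexpr(c)) == c

    def test_crossover_identical_parents_at_root_is_identity(self):
        # exchanging whole trees returns copies of the parents
        a = ("add", "x", 3)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c1, c2 = crossover(a, a, rng, CFG)
            # any subtree of a swapped with the same subtree leaves a unchanged
            # only when the chosen paths coincide; at minimum both children
            # remain legal trees built solely from a's nodes
            assert 2 <= tree_depth(c1) <= 6 and 2 <= tree_depth(c2) <= 6
        root_swap = crossover(a, a, np.random.default_rng(0), GPConfig(
            population_size=4, max_operator_retries=1))
        assert all(tree_depth(c) == 2 for c in root_swap)

    def test_mutation_single_point_and_bounds(self):
        # A root-point mutation can coincidentally keep the root operator and
        # then look like several changed branches, so the single-subtree
        # property is asserted statistically over many mutations.
        rng = np.random.default_rng(4)
        single_point = []
        for _ in range(1000):
            parent = random_tree(CFG, rng)
            child = mutate(parent, CFG, rng)
            assert 2 <= tree_depth(child) <= 6
            assert all(ERC_RANGE[0] <= v <= ERC_RANGE[1] for v in _erc_values(child))
            single_point.append(_n_differing_subtrees(parent, child) <= 1)
        assert np.mean(single_point) > 0.8

    def test_erc_mutation_changes_constant_within_range(self):
        parent = ("add", "x", 3)
        rng = np.random.default_rng(5)
        seen = set()
        for _ in range(200):
            child = mutate(parent, CFG, rng)
            for v in _erc_values(child):
                assert ERC_RANGE[0] <= v <= ERC_RANGE[1]
                seen.add(v)
        assert len(seen) > 1  # the constant does get perturbed


class TestEvolve:
    small = desk_gp_config(population_size=150, generations=10, n_runs=2)

    def test_running_best_fitness_is_non_increasing(self):
        rng = np.random.default_rng(6)
        preds = rng.uniform(0, 1, 100)
        truths = np.clip(preds + rng.normal(0, 0.1, 100), 0, 1)
        res = evolve(preds, truths, self.small, seed=1)
        for hist in res.fitness_history:
            assert len(hist) == self.small.generations
            assert np.all(np.diff(hist) <= 0)

    def test_identity_recovered_for_perfect_predictions(self):
        v = np.random.default_rng(7).uniform(0, 1, 100)
        res = evolve(v, v, self.small, seed=2)
        assert res.best_fitness < 1e-3

    def test_constant_offset_recovered(self):
        rng = np.random.default_rng(8)
        preds = rng.uniform(0, 1, 150)
        truths = preds + 3.0
        res = evolve(preds, truths, desk_gp_config(generations=15), seed=3)
        corrected = np.array(
            [evaluate_tree(res.best_tree, float(p)) for p in preds[:20]]
        )
        assert np.sqrt(np.mean((corrected - truths[:20]) ** 2)) < 3.0
        assert res.best_fitness < 1e-3  # add(x, 3) is in the search space

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            GPConfig(p_reproduction=0.6, p_crossover=0.5, p_mutation=0.15)


class TestRefine:
    def test_identity_corrections_leave_predictions_unchanged(self):
        preds = np.random.default_rng(9).uniform(0, 1, size=(20, 5))
        out = refine_predictions([identity_tree()] * 5, preds)
        np.testing.assert_allclose(out, preds)

    def test_shape_preserved_and_clipped(self):
        preds = np.full((10, 5), 0.9)
        big = ("multiply", "x", 5)
        out = refine_predictions([big] * 5, preds)
        assert out.shape == (10, 5)
        assert np.all(out == 1.0)

    def test_missing_tree_rejected(self):
        with pytest.raises(ValueError):
            refine_predictions([identity_tree()] * 4, np.zeros((3, 5)))
        with pytest.raises(ValueError):
            refine_predictions([None] * 5, np.zeros((3, 5)))
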
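"""Koza-style tree genetic programming for symbolic prediction refinement.

Stage two of the inverse solver evolves, independently per label, a small
arithmetic program f: R -> R that corrects the stage-one prediction of that
label.  Individuals are expression trees over one variable:

* function set: ``add``, ``subtract``, ``multiply``, protected ``divide``
  (returns 1 when the denominator magnitude is below 1e-6) and unary
  ``negate``;
* terminal set: the input coordinate ``x`` and integer ephemeral random
  constants (ERCs) drawn once at node creation from [-5, 5];
* tree depth between 2 and 6 levels, enforced at creation and after every
  genetic operation.

Fitness is the RMSE between f(prediction) and the true label on a freshly
drawn random 10% subsample of the training split.  Selection is size-4
tournament; each offspring event applies exactly one of reproduction
(p=0.35), subtree crossover (p=0.5) or mutation (p=0.15, including ERC
perturbation).  The best individual of each generation is carried over
unchanged (elitism), and the best individual found across all runs, judged
by its full-training-split RMSE, is the output.

Trees serialize losslessly to prefix s-expressions in JSON form, e.g.
``["add", ["multiply", "x", "x"], ["negate", ["multiply", "x", 5]]]``
for x^2 + (-5x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BINARY_OPS",
    "UNARY_OPS",
    "ERC_RANGE",
    "GPConfig",
    "GPResult",
    "desk_gp_config",
    "paper_scale_gp_config",
    "tree_depth",
    "tree_size",
    "to_sexpr",
    "from_sexpr",
    "random_tree",
    "evaluate_tree",
    "fitness",
    "tournament_select",
    "crossover",
    "mutate",
    "evolve",
    "refine_predictions",
]

BINARY_OPS = ("add", "subtract", "multiply", "divide")
UNARY_OPS = ("negate",)
ERC_RANGE = (-5, 5)  # inclusive integer range
PROTECTED_DIV_EPS = 1e-6
VARIABLE = "x"

_ARITY = {**{op: 2 for op in BINARY_OPS}, **{op: 1 for op in UNARY_OPS}}
_ALL_OPS = BINARY_OPS + UNARY_OPS


class GPStructureError(ValueError):
    """Malformed expression tree."""


# ---------------------------------------------------------------------------
# tree structure helpers
#
# A tree is either the variable string "x", an int ERC, or a tuple
# (op, child, ...) with arity matching the operator.


def _is_terminal(node) -> bool:
    return node == VARIABLE or isinstance(node, (int, np.integer))


def _validate(node) -> None:
    if _is_terminal(node):
        return
    if not (isinstance(node, tuple) and node and node[0] in _ARITY):
        raise GPStructureError(f"malformed node: {node!r}")
    if len(node) - 1 != _ARITY[node[0]]:
        raise GPStructureError(f"bad arity in node: {node!r}")
    for child in node[1:]:
        _validate(child)


def tree_depth(node) -> int:
    """Number of levels; a bare terminal has depth 1."""
    if _is_terminal(node):
        return 1
    return 1 + max(tree_depth(c) for c in node[1:])


def tree_size(node) -> int:
    if _is_terminal(node):
        return 1
    return 1 + sum(tree_size(c) for c in node[1:])


def _paths(node, prefix=()) -> list[tuple[int, ...]]:
    """All node paths in pre-order; a path is a tuple of child indices."""
    out = [prefix]
    if not _is_terminal(node):
        for i, child in enumerate(node[1:]):
            out.extend(_paths(child, prefix + (i,)))
    return out


def _get(node, path):
    for i in path:
        node = node[1 + i]
    return node


def _replace(node, path, new):
    if not path:
        return new
    i = path[0]
    children = list(node[1:])
    children[i] = _replace(children[i], path[1:], new)
    return (node[0], *children)


def to_sexpr(node):
    """Prefix s-expression (nested lists, JSON-serializable)."""
    if node == VARIABLE:
        return VARIABLE
    if isinstance(node, (int, np.integer)):
        return int(node)
    return [node[0]] + [to_sexpr(c) for c in node[1:]]


def from_sexpr(s):
    """Inverse of :func:`to_sexpr`; accepts parsed JSON or a JSON string."""
    if isinstance(s, str) and s not in (VARIABLE,):
        s = json.loads(s)
    if s == VARIABLE:
        return VARIABLE
    if isinstance(s, (int, np.integer)):
        return int(s)
    if isinstance(s, float) and s.is_integer():
        return int(s)
    if not isinstance(s, (list, tuple)) or not s:
        raise GPStructureError(f"cannot parse node {s!r}")
    return (s[0], *(from_sexpr(c) for c in s[1:]))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GPConfig:
    """Evolution parameters.

    Defaults are the full-scale settings (population 10,000, 100
    generations, 30 runs); :func:`desk_gp_config` gives the reduced budget
    used for interactive work and the test suite.
    """

    population_size: int = 10_000
    generations: int = 100
    p_reproduction: float = 0.35
    p_crossover: float = 0.5
    p_mutation: float = 0.15
    tournament_size: int = 4
    min_depth: int = 2
    max_depth: int = 6
    fitness_subsample_fraction: float = 0.10
    resample_fitness_each_generation: bool = True
    n_runs: int = 30
    max_operator_retries: int = 10

    def __post_init__(self) -> None:
        if self.p_reproduction + self.p_crossover + self.p_mutation > 1 + 1e-12:
            raise ValueError("operator probabilities must sum to <= 1")
        if min(self.p_reproduction, self.p_crossover, self.p_mutation) < 0:
            raise ValueError("operator probabilities must be >= 0")
        if self.population_size < self.tournament_size:
            raise ValueError("population_size must be >= tournament_size")
        if not (1 <= self.min_depth <= self.max_depth):
            raise ValueError("invalid depth bounds")
        if not (0 < self.fitness_subsample_fraction <= 1):
            raise ValueError("fitness_subsample_fraction must be in (0, 1]")


def desk_gp_config(**overrides) -> GPConfig:
    """Reduced-budget configuration: population 500, 30 generations, 3 runs."""
    base = dict(population_size=500, generations=30, n_runs=3)
    base.update(overrides)
    return GPConfig(**base)


def paper_scale_gp_config(**overrides) -> GPConfig:
    """Full-scale configuration (hours of CPU; not used by the test suite)."""
    return GPConfig(**overrides)


@dataclass
class GPResult:
    """Outcome of evolving one label's correction."""

    best_tree: tuple | str | int
    best_fitness: float  # RMSE of best_tree on the full training split
    fitness_history: list  # per run: list of running-best fitness per generation
    run_index: int  # which run produced best_tree
    n_nonfinite: int = 0  # individuals hitting the +inf failure sentinel

    def best_sexpr(self) -> str:
        return json.dumps(to_sexpr(self.best_tree))


# ---------------------------------------------------------------------------
# generation


def _random_terminal(rng: np.random.Generator):
    if rng.random() < 0.5:
        return VARIABLE
    return int(rng.integers(ERC_RANGE[0], ERC_RANGE[1] + 1))


def _random_subtree(rng, max_depth: int, min_depth: int, full: bool):
    """Random subtree with depth in [min_depth, max_depth]."""
    if max_depth <= 1:
        return _random_terminal(rng)
    if min_depth <= 1 and not full and rng.random() < 0.3:
        return _random_terminal(rng)
    op = _ALL_OPS[rng.integers(len(_ALL_OPS))]
    arity = _ARITY[op]
    # One child must carry the remaining minimum depth.
    deep_child = rng.integers(arity)
    children = []
    for i in range(arity):
        child_min = min_depth - 1 if i == deep_child else 1
        children.append(_random_subtree(rng, max_depth - 1, child_min, full))
    return (op, *children)


def random_tree(config: GPConfig, rng: np.random.Generator):
    """Ramped half-and-half generation within the configured depth bounds."""
    target = int(rng.integers(config.min_depth, config.max_depth + 1))
    full = bool(rng.random() < 0.5)
    return _random_subtree(rng, target, config.min_depth, full)


def identity_tree():
    """An identity-equivalent individual, add(x, 0), of minimal legal depth."""
    return ("add", VARIABLE, 0)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_tree(tree, value):
    """Evaluate the program at ``value`` (scalar or ndarray).

    Protected division returns 1 where the denominator magnitude is below
    1e-6.  Overflow and other non-finite results propagate to the caller
    (fitness maps them to the +inf sentinel).
    """
    _validate(tree)
    x = np.asarray(value, dtype=float)
    with np.errstate(all="ignore"):
        out = _eval(tree, x)
    if np.ndim(value) == 0:
        return float(out)
    return out


def _eval(node, x):
    if node == VARIABLE:
        return x
    if isinstance(node, (int, np.integer)):
        return np.broadcast_to(float(node), x.shape) if x.ndim else float(node)
    op = node[0]
    if op == "negate":
        return -_eval(node[1], x)
    a = _eval(node[1], x)
    b = _eval(node[2], x)
    if op == "add":
        return a + b
    if op == "subtract":
        return a - b
    if op == "multiply":
        return a * b
    # protected divide
    a, b = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float))
    small = np.abs(b) < PROTECTED_DIV_EPS
    safe = np.where(small, 1.0, b)
    return np.where(small, 1.0, a / safe)


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def _tree_rmse(tree, predictions, truths) -> float:
    """RMSE of the corrected predictions; +inf sentinel on non-finite output."""
    out = np.asarray(_eval_unchecked(tree, np.asarray(predictions, float)))
    if not np.all(np.isfinite(out)):
        return float("inf")
    return _rmse(out, truths)


def _eval_unchecked(tree, x):
    with np.errstate(all="ignore"):
        out = _eval(tree, x)
    return np.broadcast_to(out, x.shape) if np.ndim(out) == 0 else out


def fitness(
    tree,
    predictions: np.ndarray,
    truths: np.ndarray,
    subsample_fraction: float = 0.10,
    rng: np.random.Generator | int = 0,
) -> float:
    """Stochastic RMSE fitness on a random fraction of the data (lower is
    better); +inf if the program produces a non-finite value."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must be aligned")
    n_sub = max(1, round(subsample_fraction * len(predictions)))
    if len(predictions) == 0:
        raise ValueError("cannot evaluate fitness on an empty dataset")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.choice(len(predictions), size=n_sub, replace=False)
    return _tree_rmse(tree, predictions[idx], truths[idx])


# ---------------------------------------------------------------------------
# genetic operators


def tournament_select(population, fitnesses, k: int, rng: np.random.Generator):
    """Best of ``k`` uniform draws with replacement; ties go to the first draw."""
    if len(population) == 0:
        raise ValueError("empty population")
    if k < 1:
        raise ValueError("tournament size must be >= 1")
    idx = rng.integers(0, len(population), size=k)
    drawn = np.asarray(fitnesses, dtype=float)[idx]
    return population[idx[int(np.argmin(drawn))]]


def crossover(parent_a, parent_b, rng: np.random.Generator, config: GPConfig | None = None):
    """Subtree exchange at uniformly chosen nodes.

    Children violating the depth bounds are re-drawn a bounded number of
    times; if no legal pair is found the parents are returned as clones.
    """
    config = config or GPConfig()
    for _ in range(config.max_operator_retries):
        pa = _paths(parent_a)
        pb = _paths(parent_b)
        path_a = pa[rng.integers(len(pa))]
        path_b = pb[rng.integers(len(pb))]
        sub_a = _get(parent_a, path_a)
        sub_b = _get(parent_b, path_b)
        child_a = _replace(parent_a, path_a, sub_b)
        child_b = _replace(parent_b, path_b, sub_a)
        ok = all(
            config.min_depth <= tree_depth(c) <= config.max_depth
            for c in (child_a, child_b)
        )
        if ok:
            return child_a, child_b
    return parent_a, parent_b


def mutate(parent, config: GPConfig, rng: np.random.Generator):
    """Single-point mutation: a uniformly chosen node is replaced by a fresh
    depth-capped random subtree, or — when the chosen node is an ERC — the
    constant is perturbed to a different integer in the ERC range."""
    for _ in range(config.max_operator_retries):
        paths = _paths(parent)
        path = paths[rng.integers(len(paths))]
        node = _get(parent, path)
        if isinstance(node, (int, np.integer)):
            choices = [
                v for v in range(ERC_RANGE[0], ERC_RANGE[1] + 1) if v != int(node)
            ]
            new = int(choices[rng.integers(len(choices))])
        else:
            level = len(path) + 1  # root is level 1
            cap = config.max_depth - level + 1
            need = max(1, config.min_depth - level + 1)
            new = _random_subtree(rng, cap, need, full=False)
        child = _replace(parent, path, new)
        if config.min_depth <= tree_depth(child) <= config.max_depth:
            return child
    return parent


# ---------------------------------------------------------------------------
# the generational loop


def evolve(
    predictions: np.ndarray,
    truths: np.ndarray,
    config: GPConfig,
    seed: int = 0,
) -> GPResult:
    """Evolve a correction program for one label.

    ``predictions`` are the stage-one outputs on the GP training split and
    ``truths`` the matching normalized labels.  Runs ``config.n_runs``
    independent evolutions and returns the across-run best individual,
    judged by RMSE on the full training split (deterministic, no
    subsampling), together with each run's running-best fitness history.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape or predictions.ndim != 1:
        raise ValueError("predictions and truths must be aligned 1-D arrays")
    if len(predictions) == 0:
        raise ValueError("gp training split is empty")

    root = np.random.SeedSequence(seed)
    run_seeds = root.spawn(config.n_runs)
    histories: list[list[float]] = []
    candidates: list = []
    n_nonfinite = 0

    for run_seq in run_seeds:
        rng = np.random.default_rng(run_seq)
        population = [identity_tree()] + [
            random_tree(config, rng) for _ in range(config.population_size - 1)
        ]
        n_sub = max(1, round(config.fitness_subsample_fraction * len(predictions)))
        sub_idx = rng.choice(len(predictions), size=n_sub, replace=False)
        best_tree = None
        best_fit = float("inf")
        history = []
        for gen in range(config.generations):
            if config.resample_fitness_each_generation and gen > 0:
                sub_idx = rng.choice(len(predictions), size=n_sub, replace=False)
            xs = predictions[sub_idx]
            ys = truths[sub_idx]
            fits = np.array([_tree_rmse(t, xs, ys) for t in population])
            n_nonfinite += int(np.sum(~np.isfinite(fits)))
            gen_best = int(np.argmin(fits))
            if fits[gen_best] < best_fit:
                best_fit = float(fits[gen_best])
                best_tree = population[gen_best]
            history.append(best_fit)

            if gen == config.generations - 1:
                break
            # next generation: elite + offspring events
            new_pop = [population[gen_best]]
            while len(new_pop) < config.population_size:
                r = rng.random()
                if r < config.p_reproduction:
                    new_pop.append(
                        tournament_select(population, fits, config.tournament_size, rng)
                    )
                elif r < config.p_reproduction + config.p_crossover:
                    a = tournament_select(population, fits, config.tournament_size, rng)
                    b = tournament_select(population, fits, config.tournament_size, rng)
                    c1, c2 = crossover(a, b, rng, config)
                    new_pop.append(c1)
                    if len(new_pop) < config.population_size:
                        new_pop.append(c2)
                else:
                    parent = tournament_select(
                        population, fits, config.tournament_size, rng
                    )
                    new_pop.append(mutate(parent, config, rng))
            population = new_pop
        histories.append(history)
        candidates.append(best_tree)

    # Best across runs by full-training-split RMSE; ties to the lowest run.
    # The seeded identity individual (present in every initial population)
    # is always a candidate, so the selected correction is never worse than
    # no correction on the training split.  run_index -1 marks that case.
    candidates.append(identity_tree())
    full_scores = [_tree_rmse(t, predictions, truths) for t in candidates]
    winner = int(np.argmin(full_scores))
    return GPResult(
        best_tree=candidates[winner],
        best_fitness=float(full_scores[winner]),
        fitness_history=histories,
        run_index=winner if winner < config.n_runs else -1,
        n_nonfinite=n_nonfinite,
    )


def refine_predictions(results, predictions: np.ndarray) -> np.ndarray:
    """Apply each label's best tree to that label's stage-one predictions.

    ``results`` is a sequence of five :class:`GPResult` (or trees) in label
    order; output is clipped to the normalized [0, 1] range.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    if len(results) != predictions.shape[1]:
        raise ValueError(
            f"need one correction per label: got {len(results)} for "
            f"{predictions.shape[1]} labels"
        )
    out = np.empty_like(predictions)
    for j, res in enumerate(results):
        tree = res.best_tree if isinstance(res, GPResult) else res
        if tree is None:
            raise ValueError(f"missing correction tree for label {j}")
        col = _eval_unchecked(tree, predictions[:, j])
        out[:, j] = np.asarray(col, dtype=float)
    return np.clip(out, 0.0, 1.0)
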
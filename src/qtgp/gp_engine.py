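"""Genetic-programming symbolic regression.

A self-contained tree-based symbolic-regression engine in the style used
to derive the white-box dQTc equation: expression trees over the function
set {add, mul, neg, sin, protected exp} with indexed constant slots,
age-fitness-complexity Pareto survivor selection (with a fresh random
individual injected every generation), an optional archive-based Pareto
tournament parent-selection mode, a hard individual-size limit, periodic
elite testing on grouped cross-validation folds with random
reinitialization and derivative-free refitting of the constants, and a
final multivariate selection by generalization error, complexity and
constant count.

Trees are plain nested tuples::

    ("var", name) | ("const", k) | ("neg", t) | ("sin", t) | ("exp", t)
    | ("add", t, t) | ("mul", t, t)

``("exp", t)`` is the protected exponential (argument clamped to
[-50, 50]).  Constants live in a separate vector indexed by ``k``;
expression strings round-trip through a whitespace-separated prefix
grammar (see :func:`to_prefix` / :func:`from_prefix`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "GPConfig",
    "Individual",
    "evaluate",
    "tree_size",
    "tree_variables",
    "count_constants",
    "to_prefix",
    "from_prefix",
    "random_tree",
    "crossover",
    "mutate",
    "optimize_constants",
    "evolve",
    "select_final",
    "pareto_front",
]

_EXP_CLAMP = 50.0
UNARY_OPS = ("neg", "sin", "exp")
BINARY_OPS = ("add", "mul")


# ---------------------------------------------------------------------------
# Tree basics


def tree_size(tree) -> int:
    """Node count (the complexity measure)."""
    op = tree[0]
    if op in ("var", "const"):
        return 1
    return 1 + sum(tree_size(c) for c in tree[1:])


def tree_variables(tree) -> set:
    if tree[0] == "var":
        return {tree[1]}
    if tree[0] == "const":
        return set()
    out = set()
    for c in tree[1:]:
        out |= tree_variables(c)
    return out


def count_constants(tree) -> int:
    """Number of distinct constant slots (max index + 1)."""
    if tree[0] == "const":
        return tree[1] + 1
    if tree[0] == "var":
        return 0
    return max((count_constants(c) for c in tree[1:]), default=0)


def renumber_constants(tree, mapping=None, counter=None):
    """Renumber constant slots to 0..k-1 in depth-first order.

    Returns (new_tree, index_map) where index_map[new] = old slot index.
    """
    if mapping is None:
        mapping, counter = {}, [0]
    op = tree[0]
    if op == "const":
        old = tree[1]
        if old not in mapping:
            mapping[old] = counter[0]
            counter[0] += 1
        return ("const", mapping[old]), mapping
    if op == "var":
        return tree, mapping
    children = []
    for c in tree[1:]:
        nc, mapping = renumber_constants(c, mapping, counter)
        children.append(nc)
    return (op, *children), mapping


def evaluate(tree, constants: Sequence[float], data: Mapping[str, np.ndarray]):
    """Pointwise evaluation of a tree over columns of ``data``.

    ``data`` maps variable names to aligned numpy arrays (a DataFrame works
    too).  Unknown variable references raise KeyError; the protected
    exponential keeps every evaluation finite.
    """
    op = tree[0]
    if op == "var":
        return np.asarray(data[tree[1]], dtype=float)
    if op == "const":
        return constants[tree[1]]
    if op == "neg":
        return -evaluate(tree[1], constants, data)
    if op == "sin":
        return np.sin(evaluate(tree[1], constants, data))
    if op == "exp":
        return np.exp(np.clip(evaluate(tree[1], constants, data), -_EXP_CLAMP, _EXP_CLAMP))
    if op == "add":
        return evaluate(tree[1], constants, data) + evaluate(tree[2], constants, data)
    if op == "mul":
        return evaluate(tree[1], constants, data) * evaluate(tree[2], constants, data)
    raise ValueError(f"unknown node type {op!r}")


# ---------------------------------------------------------------------------
# Prefix-string serialization
#
# Grammar: whitespace-separated prefix tokens.  Operators appear by name
# (arity implied), variables verbatim, constant slots as "c<k>".


def to_prefix(tree) -> str:
    op = tree[0]
    if op == "var":
        return tree[1]
    if op == "const":
        return f"c{tree[1]}"
    return " ".join([op, *(to_prefix(c) for c in tree[1:])])


def from_prefix(text: str):
    tokens = text.split()

    def parse(pos):
        tok = tokens[pos]
        if tok in UNARY_OPS:
            child, pos = parse(pos + 1)
            return (tok, child), pos
        if tok in BINARY_OPS:
            left, pos = parse(pos + 1)
            right, pos = parse(pos)
            return (tok, left, right), pos
        if tok.startswith("c") and tok[1:].isdigit():
            return ("const", int(tok[1:])), pos + 1
        return ("var", tok), pos + 1

    tree, pos = parse(0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in prefix expression: {tokens[pos:]}")
    return tree


# ---------------------------------------------------------------------------
# Configuration and individuals


@dataclass(frozen=True)
class GPConfig:
    """Search configuration.

    ``size_limit`` bounds the node count of every individual (the published
    runs varied it between 10 and 100); ``elite_cadence_factor`` sets the
    elite-testing period to ``elite_cadence_factor * population_size``
    fitness evaluations; ``evaluation_budget`` is the total number of
    fitness evaluations (the published figure of 1e8 is a cluster-scale
    setting — desk-scale runs use far less).
    """

    population_size: int = 100
    evaluation_budget: int = 100_000
    size_limit: int = 64
    variables: tuple[str, ...] = ()
    constant_range: tuple[float, float] = (-10.0, 10.0)
    elite_cadence_factor: int = 1000
    n_elite: int = 5
    selection: str = "afc_pareto"  # afc_pareto | archive_tournament
    tournament_size: int = 4
    p_crossover: float = 0.7
    p_mutation: float = 0.3
    const_opt_starts: int = 5
    terminate_fitness: float | None = None

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 10 <= self.size_limit <= 100:
            raise ValueError("size_limit must lie in [10, 100]")
        if not self.variables:
            raise ValueError("config.variables must name at least one input")
        if self.selection not in ("afc_pareto", "archive_tournament"):
            raise ValueError(f"unknown selection mode {self.selection!r}")


@dataclass
class Individual:
    """A candidate equation: genotype plus bookkeeping."""

    tree: tuple
    constants: np.ndarray
    age: int = 0
    fitness: float = math.inf  # training RMSE
    cv_error: float | None = None

    @property
    def complexity(self) -> int:
        return tree_size(self.tree)

    @property
    def n_constants(self) -> int:
        return count_constants(self.tree)

    def copy(self) -> "Individual":
        return Individual(self.tree, self.constants.copy(), self.age, self.fitness, self.cv_error)


# ---------------------------------------------------------------------------
# Variation operators


def random_tree(config: GPConfig, rng: np.random.Generator, max_size: int | None = None):
    """Grow a random tree within the size limit."""
    limit = max_size if max_size is not None else config.size_limit
    target = int(rng.integers(1, max(2, limit // 2) + 1))

    def grow(budget):
        if budget <= 1 or rng.random() < 0.3:
            if rng.random() < 0.7:
                return ("var", str(rng.choice(config.variables)))
            return ("const", 0)  # renumbered later
        if rng.random() < 0.4:
            op = UNARY_OPS[rng.integers(len(UNARY_OPS))]
            return (op, grow(budget - 1))
        op = BINARY_OPS[rng.integers(len(BINARY_OPS))]
        left_budget = int(rng.integers(1, budget - 1)) if budget > 2 else 1
        return (op, grow(left_budget), grow(budget - 1 - left_budget))

    tree = grow(target)
    tree = _relabel_constants(tree, rng)
    return tree


def _relabel_constants(tree, rng):
    """Give every constant leaf its own slot, numbered depth-first."""
    counter = [0]

    def walk(t):
        if t[0] == "const":
            idx = counter[0]
            counter[0] += 1
            return ("const", idx)
        if t[0] == "var":
            return t
        return (t[0], *(walk(c) for c in t[1:]))

    return walk(tree)


def random_individual(config: GPConfig, rng: np.random.Generator) -> Individual:
    tree = random_tree(config, rng)
    lo, hi = config.constant_range
    constants = rng.uniform(lo, hi, size=count_constants(tree))
    return Individual(tree=tree, constants=constants)


def _subtrees(tree, path=()):
    yield path, tree
    if tree[0] not in ("var", "const"):
        for i, c in enumerate(tree[1:], start=1):
            yield from _subtrees(c, path + (i,))


def _replace_at(tree, path, new):
    if not path:
        return new
    i = path[0]
    children = list(tree[1:])
    children[i - 1] = _replace_at(children[i - 1], path[1:], new)
    return (tree[0], *children)


def crossover(a: tuple, b: tuple, config: GPConfig, rng: np.random.Generator, max_tries: int = 8):
    """Subtree crossover; offspring exceeding the size limit are rejected
    and the cut points resampled, falling back to a copy of ``a``."""
    a_sites = list(_subtrees(a))
    b_sites = list(_subtrees(b))
    for _ in range(max_tries):
        path, _ = a_sites[rng.integers(len(a_sites))]
        _, donor = b_sites[rng.integers(len(b_sites))]
        child = _replace_at(a, path, donor)
        if tree_size(child) <= config.size_limit:
            return _relabel_constants(child, rng)
    return _relabel_constants(a, rng)


def mutate(
    tree: tuple,
    constants: np.ndarray,
    config: GPConfig,
    rng: np.random.Generator,
    kind: str | None = None,
):
    """Mutate a genotype; returns (tree, constants).

    Kinds: "point" swaps one operator for another of the same arity,
    "subtree" replaces a random subtree with a fresh random one, "jitter"
    perturbs the constant vector without touching the structure.  When
    ``kind`` is None one is drawn at random.
    """
    if kind is None:
        kind = ("point", "subtree", "jitter")[rng.integers(3)]
    if kind == "jitter":
        if len(constants) == 0:
            return tree, constants
        scale = np.maximum(np.abs(constants), 1.0)
        return tree, constants + rng.normal(0.0, 0.1, size=len(constants)) * scale
    sites = list(_subtrees(tree))
    if kind == "point":
        ops_sites = [(p, t) for p, t in sites if t[0] not in ("var", "const")]
        if not ops_sites:
            return mutate(tree, constants, config, rng, kind="subtree")
        path, node = ops_sites[rng.integers(len(ops_sites))]
        pool = UNARY_OPS if node[0] in UNARY_OPS else BINARY_OPS
        choices = [op for op in pool if op != node[0]]
        new = (choices[rng.integers(len(choices))], *node[1:])
        out = _replace_at(tree, path, new)
    elif kind == "subtree":
        path, node = sites[rng.integers(len(sites))]
        room = config.size_limit - (tree_size(tree) - tree_size(node))
        donor = random_tree(config, rng, max_size=max(1, min(room, config.size_limit // 2)))
        out = _replace_at(tree, path, donor)
        if tree_size(out) > config.size_limit:
            out = tree
    else:
        raise ValueError(f"unknown mutation kind {kind!r}")
    out = _relabel_constants(out, rng)
    lo, hi = config.constant_range
    k = count_constants(out)
    new_constants = rng.uniform(lo, hi, size=k)
    # carry over old values where slot count allows, to keep jittered history
    m = min(k, len(constants))
    new_constants[:m] = constants[:m]
    return out, new_constants


# ---------------------------------------------------------------------------
# Constant optimization


def optimize_constants(
    tree: tuple,
    data: Mapping[str, np.ndarray],
    y: np.ndarray,
    seed: int | None = None,
    n_starts: int = 5,
    init: Sequence[float] | None = None,
    start_spread: float = 0.1,
    constant_range: tuple[float, float] = (-10.0, 10.0),
    maxiter: int | None = None,
):
    """Derivative-free refit of a tree's constants by RMSE minimization.

    Runs a bounded Nelder-Mead simplex search from ``n_starts`` random
    starting points and keeps the best.  With ``init`` given, starts are
    drawn within ``start_spread`` (relative) of it and the search is
    bounded to ±10x the initial magnitudes; otherwise starts are uniform
    in ``constant_range``.  Deterministic given ``seed``.  Returns
    (constants, rmse).
    """
    k = count_constants(tree)
    if k == 0:
        raise ValueError("tree has no constant slots to optimize")
    if seed is None:
        raise ValueError("seed is required for reproducible optimization")
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)

    def objective(c):
        pred = evaluate(tree, c, data)
        resid = pred - y
        if not np.all(np.isfinite(resid)):
            return np.inf
        return float(np.sqrt(np.mean(resid**2)))

    if init is not None:
        init = np.asarray(init, float)
        scale = np.maximum(np.abs(init), 1e-3)
        starts = [init] + [init + rng.uniform(-start_spread, start_spread, k) * scale
                           for _ in range(n_starts - 1)]
        bounds = [(-10.0 * s, 10.0 * s) for s in scale]
    else:
        lo, hi = constant_range
        starts = [rng.uniform(lo, hi, k) for _ in range(n_starts)]
        bounds = [(10.0 * lo, 10.0 * hi)] * k

    best_c, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": maxiter or 400 * k, "xatol": 1e-10, "fatol": 1e-12},
        )
        if res.fun < best_f:
            best_c, best_f = np.asarray(res.x), float(res.fun)
    if best_c is None or not np.isfinite(best_f):
        raise RuntimeError("constant optimization failed: non-finite objective at every start")
    return best_c, best_f


# ---------------------------------------------------------------------------
# Pareto machinery


def _dominates(a: tuple, b: tuple) -> bool:
    """Minimization dominance: a <= b everywhere and < somewhere."""
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def pareto_front(items: list, key: Callable) -> list:
    """Non-dominated subset of ``items`` under minimization of key(...)."""
    keys = [key(it) for it in items]
    out = []
    for i, ki in enumerate(keys):
        if not any(_dominates(kj, ki) for j, kj in enumerate(keys) if j != i):
            out.append(items[i])
    return out


def _objectives(ind: Individual) -> tuple:
    return (ind.fitness, ind.complexity, ind.age)


def _tournament(pool: list, rng, k: int) -> Individual:
    """Pareto tournament: sample k, return a non-dominated one at random."""
    picks = [pool[rng.integers(len(pool))] for _ in range(k)]
    front = pareto_front(picks, _objectives)
    return front[rng.integers(len(front))]


def _survivor_select(pool: list, size: int, rng) -> list:
    """Non-dominated sorting on (fitness, complexity, age), truncated."""
    remaining = list(pool)
    survivors: list = []
    while remaining and len(survivors) < size:
        front = pareto_front(remaining, _objectives)
        if len(survivors) + len(front) <= size:
            survivors.extend(front)
            front_ids = {id(f) for f in front}
            remaining = [r for r in remaining if id(r) not in front_ids]
        else:
            front.sort(key=lambda ind: (ind.fitness, ind.complexity))
            survivors.extend(front[: size - len(survivors)])
    return survivors


# ---------------------------------------------------------------------------
# Evolution


def _as_columns(table) -> dict:
    if isinstance(table, pd.DataFrame):
        return {c: table[c].to_numpy(float) for c in table.columns}
    return {k: np.asarray(v, float) for k, v in table.items()}


def _rmse(tree, constants, data, y) -> float:
    pred = evaluate(tree, constants, data)
    resid = np.asarray(pred, float) - y
    if not np.all(np.isfinite(resid)):
        return math.inf
    return float(np.sqrt(np.mean(resid**2)))


def _update_archive(archive: list, candidates: list) -> list:
    merged = archive + [c.copy() for c in candidates]
    front = pareto_front(merged, _objectives)
    # drop exact duplicates (same expression and fitness)
    seen, out = set(), []
    for ind in front:
        sig = (to_prefix(ind.tree), round(ind.fitness, 12))
        if sig not in seen:
            seen.add(sig)
            out.append(ind)
    return out


def _cv_error(ind: Individual, data, y, folds, seed) -> float:
    """Held-out RMSE over grouped folds, refitting constants per fold."""
    errors = []
    for f, (arm, train_idx, test_idx) in enumerate(folds):
        train = {k: v[train_idx] for k, v in data.items()}
        test = {k: v[test_idx] for k, v in data.items()}
        if ind.n_constants > 0:
            consts, _ = optimize_constants(
                ind.tree, train, y[train_idx], seed=seed + f,
                n_starts=2, init=ind.constants, maxiter=60 * max(1, ind.n_constants),
            )
        else:
            consts = ind.constants
        errors.append(_rmse(ind.tree, consts, test, y[test_idx]))
    return float(np.mean(errors))


def evolve(
    table,
    y,
    config: GPConfig,
    seed: int | None = None,
    folds=None,
    callback: Callable | None = None,
) -> list:
    """Run the evolutionary search; returns the Pareto archive.

    ``table`` holds the (scaled or raw) input columns, ``y`` the target.
    Parent selection is a Pareto tournament on (fitness, complexity, age) —
    over the population in "afc_pareto" mode, over population plus archive
    in "archive_tournament" mode.  Survivors are chosen by non-dominated
    sorting at constant population size, every generation injects one
    fresh random individual (so young lineages always re-enter), and every
    ``elite_cadence_factor * population_size`` fitness evaluations the
    current elite get their constants randomly reinitialized and refitted
    and, when ``folds`` are given, a grouped cross-validation error.
    Fully reproducible for a fixed seed.
    """
    config.validate()
    if seed is None:
        raise ValueError("seed is required for a reproducible evolution run")
    data = _as_columns(table)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)

    if config.evaluation_budget < 2 * config.population_size:
        raise ValueError("evaluation budget smaller than one generation")

    pop = [random_individual(config, rng) for _ in range(config.population_size)]
    for ind in pop:
        ind.fitness = _rmse(ind.tree, ind.constants, data, y)
    evals = len(pop)
    archive = _update_archive([], pop)

    cadence = config.elite_cadence_factor * config.population_size
    next_elite_test = cadence

    def elite_pass():
        elite = sorted(pop, key=lambda i: i.fitness)[: config.n_elite]
        for ind in elite:
            if ind.n_constants > 0:
                try:
                    consts, fit = optimize_constants(
                        ind.tree, data, y, seed=int(rng.integers(2**31 - 1)),
                        n_starts=config.const_opt_starts,
                        constant_range=config.constant_range,
                        maxiter=120 * max(1, ind.n_constants),
                    )
                except RuntimeError:
                    continue
                if fit < ind.fitness:
                    ind.constants, ind.fitness = consts, fit
            if folds is not None:
                ind.cv_error = _cv_error(ind, data, y, folds, seed=int(rng.integers(2**31 - 1)))
        return elite

    generation = 0
    while evals < config.evaluation_budget:
        parent_pool = pop + archive if config.selection == "archive_tournament" else pop
        offspring = []
        n_off = config.population_size - 1
        for _ in range(n_off):
            pa = _tournament(parent_pool, rng, config.tournament_size)
            if rng.random() < config.p_crossover:
                pb = _tournament(parent_pool, rng, config.tournament_size)
                tree = crossover(pa.tree, pb.tree, config, rng)
                lo, hi = config.constant_range
                constants = rng.uniform(lo, hi, size=count_constants(tree))
                m = min(len(constants), len(pa.constants))
                constants[:m] = pa.constants[:m]
                child = Individual(tree, constants, age=max(pa.age, 0))
            else:
                child = pa.copy()
            if rng.random() < config.p_mutation:
                child.tree, child.constants = mutate(child.tree, child.constants, config, rng)
            child.fitness = _rmse(child.tree, child.constants, data, y)
            child.cv_error = None
            offspring.append(child)
        fresh = random_individual(config, rng)
        fresh.fitness = _rmse(fresh.tree, fresh.constants, data, y)
        offspring.append(fresh)
        evals += len(offspring)

        pop = _survivor_select(pop + offspring, config.population_size, rng)
        for ind in pop:
            ind.age += 1
        archive = _update_archive(archive, pop)

        if evals >= next_elite_test:
            elite_pass()
            archive = _update_archive(archive, pop)
            next_elite_test += cadence
        generation += 1
        if callback is not None:
            callback(generation, evals, pop, archive)
        if (config.terminate_fitness is not None
                and min(i.fitness for i in archive) <= config.terminate_fitness):
            break

    elite_pass()
    archive = _update_archive(archive, pop)
    return archive


def select_final(archive: list, cv_band: float = 0.05) -> Individual:
    """Multivariate final-model selection from the archive.

    Candidates within ``cv_band`` relative of the best cross-validation
    error are considered equivalent on generalization; among them the
    lowest complexity wins, then the fewest adjustable constants.
    Requires cv_error to be populated (elite testing during evolution).
    """
    if not archive:
        raise ValueError("empty archive")
    scored = [ind for ind in archive if ind.cv_error is not None]
    if not scored:
        raise ValueError("no archive member has a cross-validation error")
    front = pareto_front(scored, lambda i: (i.cv_error, i.complexity, i.n_constants))
    best_cv = min(i.cv_error for i in front)
    band = [i for i in front if i.cv_error <= best_cv * (1.0 + cv_band)]
    band.sort(key=lambda i: (i.complexity, i.n_constants, i.cv_error))
    return band[0]
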
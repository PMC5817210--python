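"""Shared fixtures and the independent expression-evaluation oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from qtgp import preprocessing, virtual_population

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_scaler():
    return preprocessing.fit_scaler()


@pytest.fixture(scope="session")
def small_population():
    """A 2,000-record mechanistic-mode population (fixed seed)."""
    design = virtual_population.make_design(total_records=2000)
    return virtual_population.sample_population(design=design, seed=123, mode="mechanistic")


# ---------------------------------------------------------------------------
# Independent scalar evaluator for GP trees.
#
# Walks the same tuple grammar but evaluates through sympy -> plain python
# math, one point at a time — a fully separate execution path from the
# vectorized numpy recursion it is used to check.


def tree_to_sympy(tree, constants):
    import sympy as sp

    op = tree[0]
    if op == "var":
        return sp.Symbol(tree[1])
    if op == "const":
        return sp.Float(float(constants[tree[1]]), 17)
    if op == "neg":
        return -tree_to_sympy(tree[1], constants)
    if op == "sin":
        return sp.sin(tree_to_sympy(tree[1], constants))
    if op == "exp":
        arg = tree_to_sympy(tree[1], constants)
        return sp.exp(sp.Max(sp.Integer(-50), sp.Min(sp.Integer(50), arg)))
    if op == "add":
        return tree_to_sympy(tree[1], constants) + tree_to_sympy(tree[2], constants)
    if op == "mul":
        return tree_to_sympy(tree[1], constants) * tree_to_sympy(tree[2], constants)
    raise ValueError(op)


def oracle_evaluate(tree, constants, data: dict) -> np.ndarray:
    """Point-by-point scalar evaluation via sympy-lambdified python math."""
    import sympy as sp

    names = sorted({s for s in _variables(tree)})
    expr = tree_to_sympy(tree, constants)
    fn = sp.lambdify([sp.Symbol(n) for n in names], expr, modules=["math"])
    n = len(next(iter(data.values()))) if data else 1
    cols = [np.asarray(data[name], float) for name in names]
    return np.array([fn(*(c[i] for c in cols)) for i in range(n)])


def _variables(tree):
    if tree[0] == "var":
        yield tree[1]
    elif tree[0] != "const":
        for c in tree[1:]:
            yield from _variables(c)
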
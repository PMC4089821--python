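"""Shared fixtures: the packaged matrix, a cached exact search, and
small brute-force oracles used across the suite."""

import itertools
import random

import pytest

from fitchclade import (
    MISSING,
    CharacterMatrix,
    SearchConfig,
    branch_and_bound,
    load_fixture,
)
from fitchclade.datasets import OUTGROUP


@pytest.fixture(scope="session")
def fixture_matrix():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_search(fixture_matrix):
    """Exact search on the study matrix (expensive; run once)."""
    return branch_and_bound(
        fixture_matrix, SearchConfig(seed=1, starts=10, move="spr")
    )


@pytest.fixture(scope="session")
def fixture_mpt(fixture_matrix, fixture_search):
    """The unique condensed most parsimonious cladogram."""
    from fitchclade import condense

    distinct = {}
    for t in fixture_search.optimal_trees:
        c = condense(t, fixture_matrix, outgroup=OUTGROUP)
        distinct[c.to_newick()] = c
    assert len(distinct) == 1
    return next(iter(distinct.values()))


def brute_fitch_steps(tree, matrix, index):
    """Minimum changes of one character by exhaustive enumeration of
    every assignment of states to internal nodes and missing leaves.

    Independent of the Fitch implementation; tractable for <= 6 taxa
    and <= 3 states.
    """
    cells = matrix.column_cells(index)
    adj, labels = tree._adj, tree._label
    internals = [n for n in adj if n not in labels]
    states = sorted(
        {s for c in cells.values() if c is not MISSING for s in c}
    ) or [0]
    edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    leaf_nodes = list(labels)
    leaf_choices = [
        sorted(cells[labels[n]])
        if cells[labels[n]] is not MISSING
        else states
        for n in leaf_nodes
    ]
    best = None
    for internal_assign in itertools.product(states, repeat=len(internals)):
        base = dict(zip(internals, internal_assign))
        for leaf_assign in itertools.product(*leaf_choices):
            full = dict(base)
            full.update(zip(leaf_nodes, leaf_assign))
            cost = sum(
                1 for e in edges if len({full[n] for n in e}) > 1
            )
            if best is None or cost < best:
                best = cost
    return best


def random_column_matrix(taxa, rng, n_char=1, symbols="012?"):
    """Random small matrix over the given taxa for oracle tests."""
    rows = [
        "".join(rng.choice(symbols) for _ in range(n_char)) for _ in taxa
    ]
    return CharacterMatrix(taxa, rows)
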
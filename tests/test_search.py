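"""Exact and heuristic most-parsimonious-tree search."""

import random

import pytest

from fitchclade import (
    CharacterMatrix,
    SearchConfig,
    branch_and_bound,
    branch_swap,
    exhaustive_search,
    heuristic_search,
    stepwise_addition,
    tree_length,
)
from fitchclade.search import _Core, _nni_moves


class TestExhaustive:
    def test_single_informative_character_decides_four_taxa(self):
        m = CharacterMatrix(list("ABCD"), ["1", "1", "0", "0"])
        res = exhaustive_search(m)
        assert res.L_opt == 1
        assert len(res.optimal_trees) == 1
        assert frozenset("CD") in res.best_tree.bipartitions()

    def test_constant_matrix_leaves_all_topologies_optimal(self):
        m = CharacterMatrix(list("ABCDE"), ["000"] * 5)
        res = exhaustive_search(m)
        assert res.L_opt == 0
        assert len(res.optimal_trees) == 15

    def test_guard(self, fixture_matrix):
        with pytest.raises(ValueError, match="guard"):
            exhaustive_search(fixture_matrix)


class TestBranchAndBound:
    @pytest.mark.parametrize("n_taxa", [6, 7, 8])
    def test_matches_exhaustive_on_fixture_subsets(
        self, fixture_matrix, n_taxa
    ):
        """Complete optimum-set equality with the enumeration oracle on
        random taxon subsets of the study matrix."""
        rng = random.Random(n_taxa)
        for trial in range(7):
            taxa = rng.sample(fixture_matrix.taxa, n_taxa)
            sub = fixture_matrix.subset(taxa=taxa)
            ex = exhaustive_search(sub)
            bb = branch_and_bound(
                sub, SearchConfig(seed=trial, starts=3, move="spr")
            )
            assert bb.exact
            assert bb.L_opt == ex.L_opt
            assert set(bb.optimal_trees) == set(ex.optimal_trees)

    def test_degenerate_flat_landscape_reported_truthfully(self):
        """A matrix of pure autapomorphies ranks every topology equal;
        the search must report the full optimum set."""
        taxa = list("ABCDEF")
        rows = ["100000", "010000", "001000", "000100", "000010", "000001"]
        m = CharacterMatrix(taxa, rows)
        res = branch_and_bound(m, SearchConfig(seed=0, starts=2))
        assert res.L_opt == 6
        assert len(res.optimal_trees) == 105

    def test_full_matrix_optimum(self, fixture_search):
        assert fixture_search.exact
        assert fixture_search.L_opt == 57
        assert len(fixture_search.optimal_trees) == 27

    def test_taxon_input_order_irrelevant(self, fixture_matrix):
        taxa = random.Random(4).sample(fixture_matrix.taxa, 8)
        sub = fixture_matrix.subset(taxa=taxa)
        shuffled = list(taxa)
        random.Random(5).shuffle(shuffled)
        a = branch_and_bound(sub, SearchConfig(seed=0, starts=2))
        b = branch_and_bound(
            fixture_matrix.subset(taxa=shuffled),
            SearchConfig(seed=9, starts=2),
        )
        assert a.L_opt == b.L_opt
        assert set(a.optimal_trees) == set(b.optimal_trees)


class TestStepwiseAddition:
    def test_deterministic_given_seed_and_order(self, fixture_matrix):
        order = list(fixture_matrix.taxa)
        a = stepwise_addition(fixture_matrix, order=order, seed=3)
        b = stepwise_addition(fixture_matrix, order=order, seed=3)
        assert a == b

    def test_never_beats_exact_optimum(self, fixture_matrix, fixture_search):
        for seed in range(10):
            t = stepwise_addition(fixture_matrix, seed=seed)
            assert tree_length(t, fixture_matrix) >= fixture_search.L_opt

    def test_best_of_twenty_starts_reaches_the_optimum(
        self, fixture_matrix, fixture_search
    ):
        best = min(
            tree_length(
                stepwise_addition(fixture_matrix, seed=s), fixture_matrix
            )
            for s in range(20)
        )
        assert best == fixture_search.L_opt == 57


class TestBranchSwap:
    def test_optimal_tree_is_a_fixed_point(
        self, fixture_matrix, fixture_search
    ):
        t = fixture_search.best_tree
        for move in ("nni", "spr"):
            out = branch_swap(t, fixture_matrix, move=move, seed=0)
            assert tree_length(out, fixture_matrix) == 57

    @pytest.mark.parametrize("move", ["nni", "spr", "tbr"])
    def test_never_returns_a_longer_tree(self, fixture_matrix, move):
        start = stepwise_addition(fixture_matrix, seed=99)
        L0 = tree_length(start, fixture_matrix)
        out = branch_swap(start, fixture_matrix, move=move, seed=0)
        assert tree_length(out, fixture_matrix) <= L0

    def test_nni_neighborhood_size_is_2n_minus_6(self):
        """An n-leaf binary tree has exactly 2(n-3) NNI neighbors."""
        from fitchclade import random_topology

        taxa = [f"t{i}" for i in range(6)]
        m = CharacterMatrix(taxa, ["0"] * 6)
        core = _Core(m)
        adj = core.from_cladogram(random_topology(taxa, seed=0))
        moves = list(_nni_moves(adj, core.n))
        assert len(moves) == 2 * (6 - 3)
        # and they produce distinct topologies
        seen = set()
        from fitchclade.search import _swap_subtrees

        for u, a, v, b in moves:
            _swap_subtrees(adj, u, a, v, b)
            seen.add(core.to_cladogram(adj).to_newick())
            _swap_subtrees(adj, u, b, v, a)
        assert len(seen) == len(moves)


class TestHeuristicSearch:
    def test_finds_exact_optimum_over_many_starts(
        self, fixture_matrix, fixture_search
    ):
        res = heuristic_search(
            fixture_matrix, starts=50, move="spr", seed=123
        )
        assert not res.exact
        assert res.L_opt == fixture_search.L_opt

    def test_reproducible(self, fixture_matrix):
        a = heuristic_search(fixture_matrix, starts=3, move="nni", seed=7)
        b = heuristic_search(fixture_matrix, starts=3, move="nni", seed=7)
        assert a.L_opt == b.L_opt
        assert a.optimal_trees == b.optimal_trees
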
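"""Fitch step counts, their exact bounds m and g, and ensemble CI/RI."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from fitchclade import (
    CharacterMatrix,
    enumerate_topologies,
    fit_statistics,
    fitch_steps,
    max_steps,
    min_steps,
    random_topology,
    steps_vector,
    tree_length,
)
from tests.conftest import brute_fitch_steps, random_column_matrix


class TestFitchSteps:
    def test_constant_column_is_free(self):
        m = CharacterMatrix(list("ABCDE"), ["0"] * 5)
        for t in enumerate_topologies(list("ABCDE")):
            assert fitch_steps(t, m, 1) == 0

    def test_autapomorphy_costs_one_everywhere(self):
        m = CharacterMatrix(list("ABCDE"), ["1", "0", "0", "0", "0"])
        for t in enumerate_topologies(list("ABCDE")):
            assert fitch_steps(t, m, 1) == 1

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_equals_exhaustive_assignment_minimum(self, seed):
        """On small instances the Fitch pass must equal the minimum
        over every possible ancestral state assignment."""
        rng = random.Random(seed)
        taxa = list("ABCDEF")[: rng.randrange(4, 7)]
        m = random_column_matrix(taxa, rng, n_char=2)
        t = random_topology(taxa, rng=rng)
        for i in (1, 2):
            assert fitch_steps(t, m, i) == brute_fitch_steps(t, m, i)

    def test_missing_taxon_error_names_it(self, fixture_matrix):
        t = random_topology(list(fixture_matrix.taxa)[:-1], seed=0)
        with pytest.raises(ValueError, match="Selinus striatus"):
            tree_length(t, fixture_matrix)

    def test_invariance_under_taxon_order_and_char_order(
        self, fixture_matrix
    ):
        t = random_topology(fixture_matrix.taxa, seed=2)
        L = tree_length(t, fixture_matrix)
        shuffled_taxa = list(fixture_matrix.taxa)
        random.Random(0).shuffle(shuffled_taxa)
        perm = fixture_matrix.subset(taxa=shuffled_taxa)
        assert tree_length(t, perm) == L
        chars = list(range(1, 41))
        random.Random(1).shuffle(chars)
        assert tree_length(t, fixture_matrix.subset(chars=chars)) == L


class TestBounds:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_m_le_s_le_g_universally(self, seed):
        rng = random.Random(seed)
        taxa = [f"t{i}" for i in range(rng.randrange(4, 9))]
        m = random_column_matrix(taxa, rng, n_char=3)
        t = random_topology(taxa, rng=rng)
        s = steps_vector(t, m)
        for i in (1, 2, 3):
            p = m.column_profile(i)
            assert min_steps(p) <= s[i - 1] <= max_steps(p)

    @settings(max_examples=12, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_m_and_g_are_tight_over_all_topologies(self, seed):
        """min_steps/max_steps must equal the true extrema of the step
        count over every topology (exhaustive check on 6 taxa)."""
        rng = random.Random(seed)
        taxa = list("ABCDEF")
        m = random_column_matrix(taxa, rng)
        counts = [
            fitch_steps(t, m, 1) for t in enumerate_topologies(taxa)
        ]
        p = m.column_profile(1)
        assert min(counts) == min_steps(p)
        assert max(counts) == max_steps(p)

    def test_fixture_character_13_needs_two_steps(self, fixture_matrix):
        assert min_steps(fixture_matrix.column_profile(13)) == 2

    def test_fixture_bound_sums(self, fixture_matrix):
        """The CI numerator sums to 42 over the 40 characters; the RI
        denominator (star-tree maxima over taxa with data) sums to
        199.  Both follow from the per-column formulas validated
        against the exhaustive extrema above."""
        ms = [
            min_steps(fixture_matrix.column_profile(i))
            for i in range(1, 41)
        ]
        gs = [
            max_steps(fixture_matrix.column_profile(i))
            for i in range(1, 41)
        ]
        assert sum(ms) == 42
        assert sum(gs) == 199


class TestFitStatistics:
    def test_published_tree_statistics(self, fixture_matrix, fixture_search):
        acc = fit_statistics(fixture_search.best_tree, fixture_matrix)
        assert acc.L == 57
        assert acc.reported_ci == 74
        assert acc.reported_ri == 90

    def test_perfect_fit_reports_100(self):
        from fitchclade import SimulationConfig, simulate

        tree, m = simulate(
            SimulationConfig(n_taxa=8, n_char=12, regime="clean", seed=4)
        )
        acc = fit_statistics(tree, m)
        assert acc.L == acc.sum_m
        assert acc.reported_ci == 100
        assert acc.reported_ri == 100

    def test_star_worst_fit_gives_zero_ri(self):
        """When every character realizes its star-tree maximum, no
        potential synapomorphy is retained."""
        m = CharacterMatrix(list("ABCDEF"), ["01", "01", "01", "10", "10", "10"])
        worst = None
        for t in enumerate_topologies(list("ABCDEF")):
            acc = fit_statistics(t, m)
            if worst is None or acc.L > worst.L:
                worst = acc
        assert worst.L == worst.sum_g
        assert worst.ri == 0.0

    def test_ri_undefined_when_no_potential_homoplasy(self):
        m = CharacterMatrix(list("ABCD"), ["10", "01", "00", "00"])
        t = random_topology(list("ABCD"), seed=0)
        acc = fit_statistics(t, m)
        assert acc.sum_g == acc.sum_m
        assert acc.ri is None and acc.reported_ri is None
        assert "NA" in acc.to_tsv()

    def test_informative_only_flag_drops_autapomorphies(self):
        m = CharacterMatrix(
            list("ABCDE"), ["110", "100", "000", "001", "001"]
        )
        t = random_topology(list("ABCDE"), seed=1)
        full = fit_statistics(t, m)
        info = fit_statistics(t, m, informative_only=True)
        # char 2 is an autapomorphy of A: excluded by the strict flag
        assert set(full.char_ids) == {1, 2, 3}
        assert set(info.char_ids) == {1, 3}
        assert info.sum_m < full.sum_m

    def test_all_fixture_characters_are_informative(self, fixture_matrix):
        for i in range(1, 41):
            assert fixture_matrix.column_profile(i).is_informative

    def test_dendropy_agrees_on_tree_length(self, fixture_matrix):
        """Independent cross-check of the scorer against dendropy's
        parsimony implementation on an arbitrary topology."""
        import dendropy
        from dendropy.model.parsimony import parsimony_score

        from fitchclade import write_matrix

        t = random_topology(fixture_matrix.taxa, seed=9)
        ours = tree_length(t, fixture_matrix)
        ns = dendropy.TaxonNamespace()
        chars = dendropy.StandardCharacterMatrix.get(
            data=write_matrix(fixture_matrix, "nexus"),
            schema="nexus",
            taxon_namespace=ns,
        )
        dt = dendropy.Tree.get(
            data=t.to_newick(), schema="newick", taxon_namespace=ns
        )
        dt.encode_bipartitions()
        assert parsimony_score(dt, chars) == ours
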
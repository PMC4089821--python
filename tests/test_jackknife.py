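"""Character-jackknife resampling, support frequencies, consensus trees."""

import random

import pytest

from fitchclade import (
    JackknifeConfig,
    SimulationConfig,
    jackknife_matrix,
    jackknife_support,
    majority_consensus,
    random_topology,
    read_newick,
    simulate,
    strict_consensus,
)
from fitchclade.datasets import NAMED_CLADES


class TestJackknifeMatrix:
    def test_p_zero_is_identity(self, fixture_matrix):
        rep = jackknife_matrix(fixture_matrix, 0.0, random.Random(0))
        assert rep == fixture_matrix

    def test_p_one_is_degenerate(self, fixture_matrix):
        rep = jackknife_matrix(fixture_matrix, 1.0, random.Random(0))
        assert rep.n_char == 0

    def test_retained_count_matches_binomial_expectation(
        self, fixture_matrix
    ):
        rng = random.Random(42)
        draws = 3000
        total = sum(
            jackknife_matrix(fixture_matrix, 0.36, rng).n_char
            for _ in range(draws)
        )
        mean = total / draws
        # E = 40 * 0.64 = 25.6; sd of the mean ~ 0.07
        assert abs(mean - 25.6) < 0.3


class TestJackknifeSupport:
    def test_bitwise_reproducible(self, fixture_matrix):
        cfg = JackknifeConfig(replicates=20, seed=5)
        a = jackknife_support(fixture_matrix, cfg)
        b = jackknife_support(fixture_matrix, cfg)
        assert a.entries == b.entries

    def test_no_resampling_gives_full_support_for_true_clades(self):
        """With p_remove = 0 on a homoplasy-free matrix every true
        split is recovered by every replicate."""
        tree, m = simulate(
            SimulationConfig(n_taxa=8, n_char=15, regime="clean", seed=2)
        )
        tab = jackknife_support(
            m, JackknifeConfig(p_remove=0.0, replicates=10, seed=1)
        )
        for split in tree.bipartitions():
            assert tab.support_of(split) == 100.0

    def test_trivial_splits_never_reported(self, fixture_matrix):
        tab = jackknife_support(
            fixture_matrix, JackknifeConfig(replicates=10, seed=3)
        )
        for split in tab.entries:
            assert 2 <= len(split) <= len(fixture_matrix.taxa) - 2

    def test_support_decreases_with_heavier_deletion(self):
        """More character deletion cannot systematically help a clade
        present in all most-parsimonious trees."""
        tree, m = simulate(
            SimulationConfig(n_taxa=10, n_char=25, regime="clean", seed=6)
        )
        clade = max(tree.bipartitions(), key=len)
        sups = []
        for p in (0.1, 0.36, 0.6):
            tab = jackknife_support(
                m, JackknifeConfig(p_remove=p, replicates=120, seed=8)
            )
            sups.append(tab.support_of(clade))
        assert sups[0] >= sups[1] - 5.0
        assert sups[1] >= sups[2] - 5.0

    def test_master_seed_noise_is_small_for_strong_clades(
        self, fixture_matrix
    ):
        """Two independent runs agree to a few points on well-supported
        clades (binomial sampling error at this replicate count)."""
        a = jackknife_support(
            fixture_matrix, JackknifeConfig(replicates=300, seed=101)
        )
        b = jackknife_support(
            fixture_matrix, JackknifeConfig(replicates=300, seed=202)
        )
        strong = [
            s for s, v in a.entries.items() if v >= 85
        ]
        assert strong
        for s in strong:
            assert abs(a.support_of(s) - b.support_of(s)) < 6.0

    def test_support_of_accepts_either_side(self, fixture_matrix):
        tab = jackknife_support(
            fixture_matrix, JackknifeConfig(replicates=10, seed=3)
        )
        split, val = next(iter(tab.entries.items()))
        other = frozenset(fixture_matrix.taxa) - split
        assert tab.support_of(split) == tab.support_of(other) == val


class TestConsensus:
    def test_consensus_of_one_tree_is_itself(self):
        t = read_newick("((A,B),((C,D),E));")
        assert strict_consensus([t]) == t

    def test_all_three_quartets_give_star(self):
        trees = [
            read_newick("((A,B),(C,D));"),
            read_newick("((A,C),(B,D));"),
            read_newick("((A,D),(B,C));"),
        ]
        star = strict_consensus(trees)
        assert star.bipartitions() == frozenset()

    def test_split_set_is_intersection(self):
        rng = random.Random(3)
        labels = [f"t{i}" for i in range(9)]
        trees = [random_topology(labels, rng=rng) for _ in range(4)]
        cons = strict_consensus(trees)
        expected = trees[0].bipartitions()
        for t in trees[1:]:
            expected &= t.bipartitions()
        assert cons.bipartitions() == expected

    def test_majority_keeps_dominant_resolution(self):
        same = read_newick("((A,B),(C,D));")
        odd = read_newick("((A,C),(B,D));")
        maj = majority_consensus([same, same, same, odd], threshold=0.5)
        assert maj.bipartitions() == same.bipartitions()

    def test_majority_threshold_one_equals_strict(self):
        rng = random.Random(12)
        labels = [f"t{i}" for i in range(8)]
        trees = [random_topology(labels, rng=rng) for _ in range(3)]
        assert majority_consensus(trees, 1.0) == strict_consensus(trees)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            strict_consensus([])

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="leaf set"):
            strict_consensus(
                [read_newick("((A,B),(C,D));"), read_newick("((A,B),(C,E));")]
            )


class TestStudySupport:
    def test_scaled_run_brackets_the_high_support_clade(
        self, fixture_matrix
    ):
        """At 200 replicates the {crenatus, ghesquierei, modestus,
        calcaripes} clade sits within sampling error of its
        full-replicate value of about 91."""
        tab = jackknife_support(
            fixture_matrix, JackknifeConfig(replicates=200, seed=11)
        )
        val = tab.support_of(NAMED_CLADES["modestus core"])
        assert 84.0 <= val <= 98.0
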
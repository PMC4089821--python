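"""Ancestral state sets, branch transformations, clade diagnoses."""

import itertools
import random

import pytest

from fitchclade import (
    CharacterMatrix,
    MISSING,
    ancestral_sets,
    condense,
    diagnose_clade,
    map_changes,
    random_topology,
    steps_vector,
    unambiguous_changes,
)
from fitchclade.datasets import NAMED_CLADES, OUTGROUP
from tests.conftest import random_column_matrix


def brute_mpr_sets(tree, matrix, index, outgroup):
    """States attainable at each node over all minimal assignments,
    by exhaustive enumeration (independent of the DP)."""
    view = tree.rooted(outgroup)
    clades = view.clades()
    cells = matrix.column_cells(index)
    states = sorted(
        {s for c in cells.values() if c is not MISSING for s in c}
    ) or [0]
    nodes = view.postorder()
    choices = []
    for n in nodes:
        if view.children.get(n):
            choices.append(states)
        else:
            cell = cells[view.labels[n]]
            choices.append(sorted(cell) if cell is not MISSING else states)
    best = None
    per_node = {n: set() for n in nodes}
    assignments = []
    for combo in itertools.product(*choices):
        full = dict(zip(nodes, combo))
        cost = sum(
            1
            for u, v in view.branches()
            if full[u] != full[v]
        )
        assignments.append((cost, full))
        if best is None or cost < best:
            best = cost
    for cost, full in assignments:
        if cost == best:
            for n in nodes:
                per_node[n].add(full[n])
    return {clades[n]: frozenset(per_node[n]) for n in nodes}, best


class TestAncestralSets:
    def test_constant_character_fixes_the_root(self):
        m = CharacterMatrix(list("ABCDZ"), ["1"] * 5)
        t = random_topology(list("ABCDZ"), seed=0)
        sets = ancestral_sets(t, m, outgroup="Z")
        assert sets[frozenset("ABCDZ")][1] == frozenset({1})

    def test_autapomorphy_localizes_to_the_terminal_branch(self):
        m = CharacterMatrix(list("ABCDZ"), ["1", "0", "0", "0", "0"])
        t = random_topology(list("ABCDZ"), seed=1)
        rmap = unambiguous_changes(t, m, outgroup="Z")
        changes = rmap.for_char(1)
        assert len(changes) == 1
        assert changes[0].branch == frozenset("A")
        assert changes[0].unambiguous
        assert changes[0].to_states == (1,)

    @pytest.mark.parametrize("seed", range(8))
    def test_mpr_sets_match_exhaustive_enumeration(self, seed):
        """The DP's per-node attainable-state sets must equal the sets
        realized by brute-force minimal assignments."""
        rng = random.Random(seed)
        taxa = list("ABCDEZ")[: rng.randrange(5, 7)]
        taxa[-1] = "Z"
        m = random_column_matrix(taxa, rng)
        t = random_topology(taxa, rng=rng)
        expected, _ = brute_mpr_sets(t, m, 1, "Z")
        got = ancestral_sets(t, m, outgroup="Z")
        for clade, exp in expected.items():
            assert got[clade][1] == exp, (clade, exp, got[clade][1])


class TestChangeRecords:
    @pytest.mark.parametrize("seed", range(6))
    def test_unambiguous_changes_never_exceed_steps(self, seed):
        rng = random.Random(100 + seed)
        taxa = [f"t{i}" for i in range(6)] + ["Z"]
        m = random_column_matrix(taxa, rng, n_char=4)
        t = random_topology(taxa, rng=rng)
        rmap = unambiguous_changes(t, m, outgroup="Z")
        s = steps_vector(t, m)
        for i in range(1, 5):
            required = [
                r for r in rmap.for_char(i) if r.unambiguous
            ]
            assert len(required) <= s[i - 1]

    @pytest.mark.parametrize("seed", range(6))
    def test_dp_steps_agree_with_fitch(self, seed):
        rng = random.Random(200 + seed)
        taxa = [f"t{i}" for i in range(7)] + ["Z"]
        m = random_column_matrix(taxa, rng, n_char=5)
        t = random_topology(taxa, rng=rng)
        rmap = unambiguous_changes(t, m, outgroup="Z")
        assert list(rmap.accounting.s) == list(steps_vector(t, m))

    def test_homoplasy_flag_tracks_extra_steps(self, fixture_matrix, fixture_mpt):
        rmap = unambiguous_changes(fixture_mpt, fixture_matrix, OUTGROUP)
        acc = rmap.accounting
        for r in rmap.records:
            assert r.homoplasious == (
                acc.s[r.char - 1] > acc.m[r.char - 1]
            )

    def test_acctran_deltran_change_totals_equal_steps(self, fixture_matrix, fixture_search):
        t = fixture_search.best_tree
        s = steps_vector(t, fixture_matrix)
        for mapping in ("acctran", "deltran"):
            rmap = map_changes(
                t, fixture_matrix, outgroup=OUTGROUP, mapping=mapping
            )
            for i in range(1, 41):
                assert len(rmap.for_char(i)) == s[i - 1]


@pytest.fixture(scope="module")
def rmap(fixture_matrix, fixture_mpt):
    return unambiguous_changes(fixture_mpt, fixture_matrix, OUTGROUP)


class TestCladeDiagnoses:
    """The published per-clade synapomorphy/homoplasy lists, recomputed
    from the matrix on the condensed most parsimonious cladogram."""

    def diag(self, fixture_matrix, fixture_mpt, rmap, name):
        return diagnose_clade(
            fixture_mpt,
            fixture_matrix,
            NAMED_CLADES[name],
            outgroup=OUTGROUP,
            rmap=rmap,
        )

    @pytest.mark.parametrize(
        "name,syn,hom",
        [
            ("Ectateus+Selinus clade", {(12, 0), (13, 1)}, set()),
            ("Ectateus clade", {(30, 1), (33, 1)}, {(28, 0)}),
            ("Selinus clade", {(34, 1)}, {(2, 1), (6, 1)}),
            (
                "modestus group",
                {(4, 1), (8, 1), (11, 1), (13, 2), (14, 1), (19, 1), (21, 1)},
                {(15, 1)},
            ),
            ("ghesquierei+crenatus", {(22, 1), (40, 1)}, set()),
            ("modestus+calcaripes", set(), {(2, 1)}),
            ("villiersi group", {(1, 1), (17, 1), (25, 1)}, set()),
            (
                "convexipennis group",
                {(26, 1), (29, 1), (32, 1), (37, 1), (38, 1)},
                set(),
            ),
            (
                "malaisei+medius+plicicollis",
                {(24, 1), (31, 1), (37, 2)},
                {(20, 0)},
            ),
            (
                "convexipennis+laevistriatus+lamottei",
                set(),
                {(5, 1), (15, 1)},
            ),
            ("planus group", {(39, 1)}, {(10, 1), (27, 1)}),
        ],
    )
    def test_published_diagnoses(
        self, fixture_matrix, fixture_mpt, rmap, name, syn, hom
    ):
        d = self.diag(fixture_matrix, fixture_mpt, rmap, name)
        assert {
            (r.char, r.derived_state) for r in d.synapomorphies
        } == syn
        assert {(r.char, r.derived_state) for r in d.homoplasies} == hom

    def test_fragmentary_taxon_clade_diagnosis(
        self, fixture_matrix, fixture_mpt, rmap
    ):
        """The four-species clade inside the modestus group: the matrix
        implies synapomorphies 3:1 and 9:1 plus homoplasy 5:1 (char 6
        does not vary across this clade in the matrix)."""
        d = self.diag(fixture_matrix, fixture_mpt, rmap, "modestus core")
        assert {
            (r.char, r.derived_state) for r in d.synapomorphies
        } == {(3, 1), (9, 1)}
        assert {(r.char, r.derived_state) for r in d.homoplasies} == {(5, 1)}

    def test_character_15_is_homoplasious_on_two_stems(
        self, fixture_matrix, fixture_mpt, rmap
    ):
        """State 15:1 arises independently on the modestus-group stem
        and the convexipennis+laevistriatus+lamottei stem."""
        stems = {
            r.branch
            for r in rmap.for_char(15)
            if r.unambiguous and r.to_states == (1,)
        }
        assert NAMED_CLADES["modestus group"] in stems
        assert (
            NAMED_CLADES["convexipennis+laevistriatus+lamottei"] in stems
        )
        assert all(r.homoplasious for r in rmap.for_char(15))

    def test_absent_clade_is_an_error(self, fixture_matrix, fixture_mpt):
        with pytest.raises(ValueError, match="not present"):
            diagnose_clade(
                fixture_mpt,
                fixture_matrix,
                {"Selinus planus", "Zidalus latipes"},
                outgroup=OUTGROUP,
            )


class TestCondense:
    def test_all_binary_optima_share_one_condensed_topology(
        self, fixture_matrix, fixture_search, fixture_mpt
    ):
        assert len(fixture_search.optimal_trees) > 1
        for t in fixture_search.optimal_trees:
            assert condense(t, fixture_matrix, OUTGROUP) == fixture_mpt

    def test_condensed_branches_all_carry_changes(
        self, fixture_matrix, fixture_mpt
    ):
        rmap = unambiguous_changes(fixture_mpt, fixture_matrix, OUTGROUP)
        supported = {r.branch for r in rmap.records if r.unambiguous}
        view = fixture_mpt.rooted(OUTGROUP)
        clades = view.clades()
        n = fixture_mpt.n_leaves
        for _, v in view.branches():
            c = clades[v]
            if 2 <= len(c) <= n - 2:
                assert c in supported
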
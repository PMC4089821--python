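"""Ancestral states, branch transformations, and clade diagnoses.

On the tree rooted with the outgroup sister to all remaining taxa,
every character is optimized with a unit-cost dynamic program that
yields, for each branch and each pair of endpoint states, the minimum
tree length subject to fixing those endpoints.  From these exact
tables the module derives:

* the set of states attainable at each node in *some* most
  parsimonious reconstruction (MPR sets);
* the branches on which a character changes in *every* MPR
  ("unambiguous" transformations — the mapping usually drawn as
  circles on published cladograms), with from/to states where they
  are uniquely determined;
* the homoplasy status of each transformation: a character whose
  observed steps exceed its minimum changes more than once on the
  tree, so none of its transformations is a unique origin;
* per-clade diagnoses (synapomorphies and homoplasious support of the
  clade's stem branch);
* a condensed tree in which internal branches whose minimum length is
  zero (no character changes on them in at least one MPR) are
  collapsed — the convention under which an exact search is said to
  yield "a single most parsimonious cladogram" even when many binary
  resolutions tie.

ACCTRAN and DELTRAN single-reconstruction mappings are available as
alternatives; ties are resolved toward (ACCTRAN) or away from
(DELTRAN) placing a change on the branch nearer the root, then by
smallest state code, so outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .fitch import StepAccounting, max_steps, min_steps
from .matrix import MISSING, CharacterMatrix
from .tree import Cladogram, RootedView

__all__ = [
    "ChangeRecord",
    "ReconstructionMap",
    "CladeDiagnosis",
    "ancestral_sets",
    "unambiguous_changes",
    "classify_homoplasy",
    "diagnose_clade",
    "map_changes",
    "condense",
]

_INF = 10**9


@dataclass(frozen=True)
class ChangeRecord:
    """One character transformation on one branch.

    ``branch`` is the clade (leaf set) below the branch; ``from_states``
    / ``to_states`` are the endpoint states over all most-parsimonious
    reconstructions exhibiting the change (singletons when uniquely
    determined).  ``unambiguous`` marks changes present in every MPR.
    ``homoplasious`` is a character-level flag: the character needs
    more steps on this tree than its theoretical minimum, so the
    change is not a unique origin.
    """

    branch: frozenset
    char: int  # 1-based
    from_states: tuple
    to_states: tuple
    unambiguous: bool
    homoplasious: bool

    @property
    def derived_state(self) -> int | None:
        return self.to_states[0] if len(self.to_states) == 1 else None

    def __str__(self) -> str:
        frm = "/".join(map(str, self.from_states))
        to = "/".join(map(str, self.to_states))
        flag = "" if self.unambiguous else "?"
        h = "*" if self.homoplasious else ""
        return f"{self.char}:{frm}->{to}{flag}{h}"


@dataclass(frozen=True)
class ReconstructionMap:
    """All transformations of a matrix on one rooted tree."""

    tree: Cladogram
    outgroup: str
    records: tuple
    accounting: StepAccounting

    def on_branch(self, clade: frozenset, unambiguous_only: bool = True):
        clade = frozenset(clade)
        return tuple(
            r
            for r in self.records
            if r.branch == clade and (r.unambiguous or not unambiguous_only)
        )

    def for_char(self, char: int):
        return tuple(r for r in self.records if r.char == char)

    def to_tsv(self) -> str:
        lines = ["branch\tchar\tfrom\tto\tunambiguous\thomoplasious"]
        for r in sorted(
            self.records, key=lambda r: (sorted(r.branch), r.char)
        ):
            lines.append(
                "{}\t{}\t{}\t{}\t{}\t{}".format(
                    ",".join(sorted(r.branch)),
                    r.char,
                    "/".join(map(str, r.from_states)),
                    "/".join(map(str, r.to_states)),
                    int(r.unambiguous),
                    int(r.homoplasious),
                )
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CladeDiagnosis:
    """Characters with an unambiguous change on a clade's stem branch."""

    clade: frozenset
    supporting: tuple  # of ChangeRecord

    @property
    def synapomorphies(self) -> tuple:
        return tuple(r for r in self.supporting if not r.homoplasious)

    @property
    def homoplasies(self) -> tuple:
        return tuple(r for r in self.supporting if r.homoplasious)

    def __str__(self) -> str:
        items = ", ".join(
            f"{r.char}:{r.derived_state if r.derived_state is not None else '?'}"
            + ("*" if r.homoplasious else "")
            for r in self.supporting
        )
        return f"[{len(self.clade)} taxa] {items or '(none)'}"


# ---------------------------------------------------------------------------
# unit-cost Sankoff tables


def _char_alphabet(matrix: CharacterMatrix, index: int) -> list:
    states = sorted(matrix.column_profile(index).observed_states)
    return states or [0]


def _down_tables(view: RootedView, matrix: CharacterMatrix, index: int):
    """Subtree cost table down[v][s] for one character."""
    states = _char_alphabet(matrix, index)
    k = len(states)
    pos = {s: i for i, s in enumerate(states)}
    cells = matrix.column_cells(index)
    down: dict = {}
    for v in view.postorder():
        kids = view.children.get(v, ())
        if not kids:
            cell = cells[view.labels[v]]
            row = np.full(k, _INF, dtype=np.int64)
            if cell is MISSING:
                row[:] = 0
            else:
                for s in cell:
                    row[pos[s]] = 0
            down[v] = row
        else:
            row = np.zeros(k, dtype=np.int64)
            for c in kids:
                row = row + _cmin(down[c])
            down[v] = row
    return states, down


def _cmin(costs: np.ndarray) -> np.ndarray:
    """min over r of costs[r] + [r != t], as a vector over t."""
    return np.minimum(costs, costs.min() + 1)


def _rest_tables(view: RootedView, down: dict):
    """rest[v][s]: min cost of the tree outside v's subtree, with v's
    parent-facing endpoint forced to state s (edge above v included)."""
    rest = {view.root: np.zeros_like(down[view.root])}
    order = view.postorder()[::-1]  # preorder
    for u in order:
        kids = view.children.get(u, ())
        for v in kids:
            sib = np.zeros_like(down[u])
            for w in kids:
                if w is not v:
                    sib = sib + _cmin(down[w])
            base = rest[u] + sib  # cost outside v given u's state
            rest[v] = _cmin(base)
    return rest


def _char_tables(view: RootedView, matrix: CharacterMatrix, index: int):
    states, down = _down_tables(view, matrix, index)
    rest = _rest_tables(view, down)
    L = int(down[view.root].min())
    return states, down, rest, L


def ancestral_sets(
    tree: Cladogram,
    matrix: CharacterMatrix,
    outgroup: str | None = None,
) -> dict:
    """MPR state sets per node and character.

    Returns ``{clade: {char: frozenset(states)}}`` keyed by the leaf
    set below each node of the rooted view; a state belongs to a
    node's set iff some most-parsimonious reconstruction assigns it
    there.  Leaves carry their own cell (full alphabet if missing).
    """
    view = tree.rooted(outgroup)
    clades = view.clades()
    out: dict = {clades[v]: {} for v in view.postorder()}
    for index in range(1, matrix.n_char + 1):
        states, down, rest, L = _char_tables(view, matrix, index)
        for v in view.postorder():
            total = down[v] + rest[v]
            keep = frozenset(
                s for s, c in zip(states, total) if c == L
            )
            out[clades[v]][index] = keep
    return out


def _branch_records(
    view: RootedView,
    clades: dict,
    matrix: CharacterMatrix,
    index: int,
    homoplasious: bool,
):
    """Change records of one character over all branches; returns
    (records, steps) with steps the character's length on this tree."""
    states, down, rest, L = _char_tables(view, matrix, index)
    k = len(states)
    records = []
    for u, v in view.branches():
        # joint endpoint costs J[a, b] for edge (u, v): everything
        # outside v's subtree with u = a, plus v's subtree with v = b,
        # plus the edge itself
        kids = view.children[u]
        sib = np.zeros(k, dtype=np.int64)
        for w in kids:
            if w is not v:
                sib = sib + _cmin(down[w])
        outside = (
            np.zeros(k, dtype=np.int64) if u is view.root else rest[u]
        )
        above = outside + sib  # cost of everything but v's subtree, u=a
        J = (
            above[:, None]
            + down[v][None, :]
            + (1 - np.eye(k, dtype=np.int64))
        )
        best = int(J.min())
        if best != L:  # numerical sanity: tables must agree
            raise AssertionError("inconsistent DP tables")
        same_min = int(np.diag(J).min()) if k else 0
        diff = J + np.eye(k, dtype=np.int64) * _INF
        diff_min = int(diff.min())
        if diff_min > L:
            continue  # this branch never changes in any MPR
        pairs = [
            (states[a], states[b])
            for a in range(k)
            for b in range(k)
            if a != b and J[a, b] == L
        ]
        records.append(
            ChangeRecord(
                branch=clades[v],
                char=index,
                from_states=tuple(sorted({a for a, _ in pairs})),
                to_states=tuple(sorted({b for _, b in pairs})),
                unambiguous=same_min > L,
                homoplasious=homoplasious,
            )
        )
    return records, L


def unambiguous_changes(
    tree: Cladogram,
    matrix: CharacterMatrix,
    outgroup: str | None = None,
) -> ReconstructionMap:
    """All branch transformations, flagged unambiguous/ambiguous.

    A branch carries an unambiguous change for a character iff every
    most-parsimonious reconstruction assigns different states to its
    endpoints; ambiguous records (change in some but not all MPRs)
    are included with ``unambiguous=False``.
    """
    view = tree.rooted(outgroup)
    clades = view.clades()
    records = []
    steps = []
    for index in range(1, matrix.n_char + 1):
        recs, s_i = _branch_records(view, clades, matrix, index, False)
        records.extend(recs)
        steps.append(s_i)
    acc = _dp_accounting(matrix, steps)
    rmap = ReconstructionMap(
        tree=tree,
        outgroup=view.outgroup,
        records=tuple(records),
        accounting=acc,
    )
    return classify_homoplasy(rmap, acc)


def _dp_accounting(matrix: CharacterMatrix, steps: list) -> StepAccounting:
    """Step accounting with observed steps taken from the DP, so it is
    valid for multifurcating (consensus/condensed) trees as well."""
    cols = [matrix.column_profile(i) for i in range(1, matrix.n_char + 1)]
    return StepAccounting(
        char_ids=tuple(range(1, matrix.n_char + 1)),
        s=np.asarray(steps, dtype=np.int64),
        m=np.asarray([min_steps(c) for c in cols], dtype=np.int64),
        g=np.asarray([max_steps(c) for c in cols], dtype=np.int64),
    )


def classify_homoplasy(
    rmap: ReconstructionMap, accounting: StepAccounting
) -> ReconstructionMap:
    """Re-flag records from a step accounting: a change is
    non-homoplasious iff its character attains its minimum steps on
    this tree (single origin)."""
    lookup = {
        cid: (int(s) > int(m))
        for cid, s, m in zip(
            accounting.char_ids, accounting.s, accounting.m
        )
    }
    new = tuple(
        replace(r, homoplasious=lookup.get(r.char, r.homoplasious))
        for r in rmap.records
    )
    return replace(rmap, records=new, accounting=accounting)


def diagnose_clade(
    tree: Cladogram,
    matrix: CharacterMatrix,
    clade: Iterable[str],
    outgroup: str | None = None,
    rmap: ReconstructionMap | None = None,
) -> CladeDiagnosis:
    """Characters with an unambiguous change on the clade's stem branch.

    Raises ``ValueError`` when the clade is not a branch of the rooted
    tree (distinct from a present clade with an empty diagnosis).
    """
    clade = frozenset(clade)
    view = tree.rooted(outgroup)
    clades = set(view.clades().values())
    if clade not in clades:
        raise ValueError(
            f"clade {sorted(clade)} is not present in the tree"
        )
    if rmap is None:
        rmap = unambiguous_changes(tree, matrix, outgroup)
    return CladeDiagnosis(
        clade=clade, supporting=rmap.on_branch(clade, unambiguous_only=True)
    )


# ---------------------------------------------------------------------------
# single-reconstruction mappings (ACCTRAN / DELTRAN)


def map_changes(
    tree: Cladogram,
    matrix: CharacterMatrix,
    outgroup: str | None = None,
    mapping: str = "unambiguous",
) -> ReconstructionMap:
    """Branch-change map under a resolution policy.

    ``"unambiguous"`` (default) reports exactly the changes common to
    all MPRs plus ambiguous candidates (see
    :func:`unambiguous_changes`).  ``"acctran"``/``"deltran"`` commit
    to one reconstruction and report its changes, all flagged
    unambiguous within that reconstruction.
    """
    if mapping == "unambiguous":
        return unambiguous_changes(tree, matrix, outgroup)
    if mapping not in ("acctran", "deltran"):
        raise ValueError(f"unknown mapping {mapping!r}")
    view = tree.rooted(outgroup)
    clades = view.clades()
    records = []
    steps = []
    prefer_change = mapping == "acctran"
    for index in range(1, matrix.n_char + 1):
        states, down = _down_tables(view, matrix, index)
        steps.append(int(down[view.root].min()))
        assign: dict = {}
        root_costs = down[view.root]
        assign[view.root] = states[int(np.argmin(root_costs))]
        for u in view.postorder()[::-1]:  # preorder
            for v in view.children.get(u, ()):
                a = assign[u]
                costs = down[v] + np.array(
                    [0 if s == a else 1 for s in states], dtype=np.int64
                )
                best = int(costs.min())
                ties = [s for s, c in zip(states, costs) if c == best]
                if a in ties and not prefer_change:
                    choice = a
                elif prefer_change and any(s != a for s in ties):
                    choice = min(s for s in ties if s != a)
                else:
                    choice = a if a in ties else min(ties)
                assign[v] = choice
                if choice != a:
                    records.append(
                        ChangeRecord(
                            branch=clades[v],
                            char=index,
                            from_states=(a,),
                            to_states=(choice,),
                            unambiguous=True,
                            homoplasious=False,
                        )
                    )
    acc = _dp_accounting(matrix, steps)
    rmap = ReconstructionMap(
        tree=tree, outgroup=view.outgroup, records=tuple(records),
        accounting=acc,
    )
    return classify_homoplasy(rmap, acc)


# ---------------------------------------------------------------------------
# zero-length-branch collapsing


def condense(
    tree: Cladogram,
    matrix: CharacterMatrix,
    outgroup: str | None = None,
    rmap: ReconstructionMap | None = None,
) -> Cladogram:
    """Collapse internal branches of minimum length zero.

    A branch's minimum length is the number of characters changing on
    it in every MPR; branches where no character is forced to change
    can be contracted without affecting the tree length, which is the
    usual convention for counting distinct most-parsimonious
    cladograms from an exact search.  The result may be
    multifurcating.
    """
    if rmap is None:
        rmap = unambiguous_changes(tree, matrix, outgroup)
    og = outgroup or tree.outgroup
    supported = {
        r.branch for r in rmap.records if r.unambiguous
    }

    def as_clade(split: frozenset) -> frozenset:
        # orient a split as the side not containing the outgroup, the
        # orientation under which branch records are keyed
        if og is not None and og in split:
            return frozenset(tree.leaves) - split
        return split

    keep = [s for s in tree.bipartitions() if as_clade(s) in supported]
    return Cladogram.from_splits(tree.leaves, keep, outgroup=og)
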
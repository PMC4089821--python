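"""Fitch parsimony scoring and ensemble fit statistics (CI, RI).

For an unordered character, the minimum number of state changes on a
binary tree is computed by the classic set intersection/union
post-order pass; its value does not depend on where the tree is rooted.
The ensemble consistency index CI = sum(m_i)/L and retention index
RI = (sum(g_i) - L)/(sum(g_i) - sum(m_i)) summarize homoplasy, where
for each character i

* ``m_i`` — minimum steps on any tree: (number of observed states) - 1,
* ``s_i`` — observed steps on the scored tree,
* ``g_i`` — maximum steps on any tree: observed taxa minus the largest
  single-state class (the star-tree value).

Characters with no variation (or no data) have m = s = g = 0 and drop
out of all sums.  All variable characters are included, also
parsimony-uninformative ones (an ``informative_only`` flag computes the
stricter convention for comparison).  Reported CI/RI follow the common
publication convention: value x 100, rounded half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._encode import encode_matrix
from .matrix import CharacterColumn, CharacterMatrix
from .tree import Cladogram

__all__ = [
    "fitch_steps",
    "steps_vector",
    "tree_length",
    "min_steps",
    "max_steps",
    "fit_statistics",
    "StepAccounting",
]


def _check_leaf_sets(tree: Cladogram, matrix: CharacterMatrix) -> None:
    tl, ml = tree.leaves, set(matrix.taxa)
    if tl != ml:
        missing = sorted(ml - tl)
        extra = sorted(tl - ml)
        if missing:
            raise ValueError(f"taxa absent from tree: {missing}")
        raise ValueError(f"tree leaves absent from matrix: {extra}")


def _postorder_arrays(tree: Cladogram):
    """Root on an arbitrary leaf edge; return traversal for downpass.

    Returns (leaf_nodes, order) where order is a list of
    (node, left_child, right_child) in postorder, plus the top leaf and
    the subtree-root node whose sets meet across the root edge.
    """
    if not tree.is_binary:
        raise ValueError("Fitch scoring requires a binary tree")
    top = next(iter(tree._leaf_of.values()))
    adj, labels = tree._adj, tree._label
    start = adj[top][0]
    parent = {start: top}
    stack, order = [start], []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v != parent.get(u):
                parent[v] = u
                stack.append(v)
    order.reverse()
    steps = []
    for u in order:
        if u in labels:
            continue
        kids = [v for v in adj[u] if v != parent[u]]
        steps.append((u, kids[0], kids[1]))
    return top, start, steps


def steps_vector(tree: Cladogram, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character Fitch step counts of ``matrix`` on ``tree``."""
    _check_leaf_sets(tree, matrix)
    if matrix.n_taxa == 1:
        return np.zeros(matrix.n_char, dtype=np.int64)
    masks = encode_matrix(matrix)
    node_of = {t: tree._leaf_of[t] for t in matrix.taxa}
    sets: dict = {}
    for i, t in enumerate(matrix.taxa):
        sets[node_of[t]] = masks[i]
    steps = np.zeros(matrix.n_char, dtype=np.int64)
    if matrix.n_taxa == 2:
        a, b = (sets[n] for n in sets)
        return steps + ((a & b) == 0)
    top, start, order = _postorder_arrays(tree)
    for node, left, right in order:
        inter = sets[left] & sets[right]
        empty = inter == 0
        steps += empty
        sets[node] = np.where(empty, sets[left] | sets[right], inter)
    steps += (sets[start] & sets[top]) == 0
    return steps


def fitch_steps(tree: Cladogram, matrix: CharacterMatrix, index: int) -> int:
    """Minimum changes of character ``index`` (1-based) on ``tree``."""
    matrix._check_index(index)
    return int(steps_vector(tree, matrix)[index - 1])


def tree_length(tree: Cladogram, matrix: CharacterMatrix) -> int:
    """Parsimony length L: total Fitch steps over all characters."""
    return int(steps_vector(tree, matrix).sum())


def min_steps(column: CharacterColumn) -> int:
    """Minimum steps on any tree: observed states minus one."""
    return max(0, len(column.observed_states) - 1)


def max_steps(column: CharacterColumn) -> int:
    """Maximum steps on any tree (star-tree value) for an unordered
    character: observed taxa minus the largest single-state class."""
    if not column.counts:
        return 0
    return column.n_observed - max(column.counts.values())


def _report(value: float | None) -> int | None:
    if value is None:
        return None
    return int(math.floor(abs(value) * 100 + 0.5)) * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class StepAccounting:
    """Per-character step accounting and ensemble CI/RI for one tree."""

    char_ids: tuple  # 1-based
    s: np.ndarray  # observed steps on the tree
    m: np.ndarray  # per-character minima
    g: np.ndarray  # per-character maxima

    @property
    def L(self) -> int:
        return int(self.s.sum())

    @property
    def sum_m(self) -> int:
        return int(self.m.sum())

    @property
    def sum_g(self) -> int:
        return int(self.g.sum())

    @property
    def ci(self) -> float | None:
        return self.sum_m / self.L if self.L > 0 else None

    @property
    def ri(self) -> float | None:
        if self.sum_g == self.sum_m:
            return None  # no potential homoplasy: RI undefined
        return (self.sum_g - self.L) / (self.sum_g - self.sum_m)

    @property
    def reported_ci(self) -> int | None:
        """CI x 100 rounded half away from zero (publication style)."""
        return _report(self.ci)

    @property
    def reported_ri(self) -> int | None:
        return _report(self.ri)

    def to_tsv(self) -> str:
        lines = ["char\tm\ts\tg\tci\tri"]
        for cid, m, s, g in zip(self.char_ids, self.m, self.s, self.g):
            ci = f"{m / s:.4f}" if s > 0 else "NA"
            ri = f"{(g - s) / (g - m):.4f}" if g > m else "NA"
            lines.append(f"{cid}\t{m}\t{s}\t{g}\t{ci}\t{ri}")
        lines.append(
            f"total\t{self.sum_m}\t{self.L}\t{self.sum_g}"
            f"\t{'NA' if self.ci is None else f'{self.ci:.4f}'}"
            f"\t{'NA' if self.ri is None else f'{self.ri:.4f}'}"
        )
        return "\n".join(lines) + "\n"


def fit_statistics(
    tree: Cladogram,
    matrix: CharacterMatrix,
    informative_only: bool = False,
) -> StepAccounting:
    """Score ``tree`` and assemble CI/RI ingredients.

    With ``informative_only=True`` the sums run over parsimony-
    informative characters only (an alternative convention; the default
    includes every variable character).
    """
    s = steps_vector(tree, matrix)
    cols = [matrix.column_profile(i) for i in range(1, matrix.n_char + 1)]
    m = np.array([min_steps(c) for c in cols], dtype=np.int64)
    g = np.array([max_steps(c) for c in cols], dtype=np.int64)
    keep = np.ones(len(cols), dtype=bool)
    if informative_only:
        keep = np.array([c.is_informative for c in cols], dtype=bool)
    ids = tuple(
        i for i, k in zip(range(1, matrix.n_char + 1), keep) if k
    )
    return StepAccounting(ids, s[keep], m[keep], g[keep])
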
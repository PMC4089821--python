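"""Most-parsimonious tree search.

Two engines over the same scoring core:

* :func:`branch_and_bound` — exact search by implicit enumeration.
  Taxa are added one at a time on every edge of every partial tree;
  a branch of the enumeration is abandoned as soon as the partial
  length plus an admissible lower bound for the unplaced taxa exceeds
  the incumbent.  Seeded with a stepwise-addition + branch-swapping
  incumbent, the 20-taxon study matrix completes in seconds and the
  full set of optimal topologies is returned.
* :func:`heuristic_search` — random-addition-sequence stepwise
  addition followed by hill-climbing branch swapping (NNI, SPR or
  TBR), the workhorse inside jackknife resampling.

Scoring uses bitmask Fitch passes over parsimony-informative columns
only (deduplicated, with multiplicities); uninformative variable
characters contribute a topology-independent constant that is added
back to every reported length.  Edge-insertion costs are computed
exactly in one pass from the directed Fitch sets of the current tree:
attaching a leaf (or pruned subtree) with state set X on edge e costs
one extra step precisely for the characters where X is disjoint from
the optimal state set of e's midpoint.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

import numpy as np

from ._encode import POPCOUNT, dedupe_columns, encode_matrix
from .fitch import min_steps
from .matrix import CharacterMatrix
from .tree import Cladogram, enumerate_topologies

__all__ = [
    "SearchConfig",
    "SearchResult",
    "branch_and_bound",
    "exhaustive_search",
    "heuristic_search",
    "stepwise_addition",
    "branch_swap",
]

EXHAUSTIVE_GUARD = 10


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of a parsimony search.

    ``starts`` random-addition sequences feed ``move`` branch swapping;
    for the exact search these only build the initial upper bound.
    """

    addition_order: str = "distinctness"  # distinctness | input | random
    move: str = "tbr"  # nni | spr | tbr
    starts: int = 10
    seed: int | None = None
    exact: bool = True


@dataclass(frozen=True)
class SearchResult:
    optimal_trees: tuple
    L_opt: int
    n_evaluated: int
    exact: bool

    @property
    def best_tree(self) -> Cladogram:
        return self.optimal_trees[0]

    def __repr__(self) -> str:
        kind = "exact" if self.exact else "heuristic"
        return (
            f"<SearchResult {kind}: L={self.L_opt}, "
            f"{len(self.optimal_trees)} optimal tree(s), "
            f"{self.n_evaluated} evaluations>"
        )


# ---------------------------------------------------------------------------
# scoring core on adjacency dicts


class _Core:
    """Encoded matrix + mutable tree machinery shared by all engines.

    Leaves are 0..n-1 in matrix taxon order; internal node ids start
    at n.  Only parsimony-informative column patterns are scored;
    ``offset`` restores the constant contribution of uninformative
    variable characters.
    """

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.taxa = matrix.taxa
        self.n = matrix.n_taxa
        self.evals = 0  # number of (partial) trees scored
        full = encode_matrix(matrix)
        profiles = [
            matrix.column_profile(i) for i in range(1, matrix.n_char + 1)
        ]
        informative = np.array(
            [p.is_informative for p in profiles], dtype=bool
        )
        self.offset = int(
            sum(min_steps(p) for p, k in zip(profiles, informative) if not k)
        )
        masks, weights = dedupe_columns(full[:, informative])
        self.masks = masks  # (n_taxa, n_patterns)
        self.weights = weights
        # definite-state masks for lower bounds: in an informative
        # column a cell is definite iff its mask is a single bit
        # (missing/polymorphic cells span >= 2 states there)
        self.defmasks = np.where(
            POPCOUNT[masks] == 1, masks, 0
        ).astype(np.uint8)

    # -- tree plumbing ---------------------------------------------------

    def star(self, a: int, b: int, c: int) -> dict:
        hub = self.n
        return {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}

    @staticmethod
    def insert(adj: dict, leaf: int, edge: tuple, new_internal: int) -> None:
        u, v = edge
        adj[u] = [x if x != v else new_internal for x in adj[u]]
        adj[v] = [x if x != u else new_internal for x in adj[v]]
        adj[new_internal] = [u, v, leaf]
        adj[leaf] = [new_internal]

    @staticmethod
    def remove_leaf(adj: dict, leaf: int) -> tuple:
        """Undo :meth:`insert`; returns the restored edge."""
        w = adj[leaf][0]
        u, v = (x for x in adj[w] if x != leaf)
        adj[u] = [x if x != w else v for x in adj[u]]
        adj[v] = [x if x != w else u for x in adj[v]]
        del adj[w], adj[leaf]
        return (u, v)

    def to_cladogram(self, adj: dict, outgroup: str | None = None) -> Cladogram:
        labels = {i: self.taxa[i] for i in adj if i < self.n}
        return Cladogram(adj, labels, outgroup=outgroup)

    def from_cladogram(self, tree: Cladogram) -> dict:
        node_id = {}
        for i, t in enumerate(self.taxa):
            node_id[tree._leaf_of[t]] = i
        nxt = self.n
        for u in tree._adj:
            if u not in node_id:
                node_id[u] = nxt
                nxt += 1
        return {
            node_id[u]: [node_id[v] for v in nb]
            for u, nb in tree._adj.items()
        }

    # -- Fitch machinery -------------------------------------------------

    def _traverse(self, adj: dict, root_leaf: int):
        start = adj[root_leaf][0]
        parent = {start: root_leaf}
        pre = [start]
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    pre.append(v)
                    stack.append(v)
        return start, parent, pre

    def score(self, adj: dict) -> int:
        """Weighted informative length of the (binary) tree plus offset."""
        self.evals += 1
        leaves = [u for u in adj if u < self.n]
        if len(leaves) < 3:
            return self.offset
        root_leaf = leaves[0]
        start, parent, pre = self._traverse(adj, root_leaf)
        D: dict = {}
        total = 0
        for u in reversed(pre):
            if u < self.n:
                D[u] = self.masks[u]
                continue
            k1, k2 = (v for v in adj[u] if v != parent[u])
            inter = D[k1] & D[k2]
            empty = inter == 0
            total += int(self.weights[empty].sum())
            D[u] = np.where(empty, D[k1] | D[k2], inter)
        total += int(self.weights[(D[start] & self.masks[root_leaf]) == 0].sum())
        return total + self.offset

    def edge_sets(self, adj: dict, exclude: set | None = None):
        """Directed Fitch sets and per-edge midpoint state sets.

        Returns (L, edges, midsets) where edges[i] = (parent, child)
        and midsets[i] is the set of states assignable at a point
        subdividing that edge in some most-parsimonious labeling.
        ``L`` includes the uninformative offset.  ``exclude`` names
        nodes of a detached component to ignore when picking the
        traversal root.
        """
        leaves = [
            u
            for u in adj
            if u < self.n and (exclude is None or u not in exclude)
        ]
        root_leaf = leaves[0]
        start, parent, pre = self._traverse(adj, root_leaf)
        D: dict = {}
        total = 0
        for u in reversed(pre):
            if u < self.n:
                D[u] = self.masks[u]
                continue
            k1, k2 = (v for v in adj[u] if v != parent[u])
            inter = D[k1] & D[k2]
            empty = inter == 0
            total += int(self.weights[empty].sum())
            D[u] = np.where(empty, D[k1] | D[k2], inter)
        total += int(self.weights[(D[start] & self.masks[root_leaf]) == 0].sum())
        U: dict = {start: self.masks[root_leaf]}
        for u in pre:
            if u < self.n:
                continue
            k1, k2 = (v for v in adj[u] if v != parent[u])
            for v, w in ((k1, k2), (k2, k1)):
                inter = U[u] & D[w]
                U[v] = np.where(inter == 0, U[u] | D[w], inter)
        edges, midsets = [], []
        for v in pre:
            inter = D[v] & U[v]
            mid = np.where(inter == 0, D[v] | U[v], inter)
            edges.append((parent[v], v))
            midsets.append(mid)
        return total + self.offset, edges, midsets

    def insertion_costs(
        self, adj: dict, x_mask: np.ndarray, exclude: set | None = None
    ):
        """Exact extra length of attaching state-set ``x_mask`` on each
        edge; returns (L, edges, costs)."""
        L, edges, midsets = self.edge_sets(adj, exclude=exclude)
        self.evals += len(edges)
        costs = [
            int(self.weights[(x_mask & mid) == 0].sum()) for mid in midsets
        ]
        return L, edges, costs

    def subtree_down(self, adj: dict, away: int, top: int):
        """Downpass set and internal steps of the subtree containing
        ``top`` after cutting edge (away, top)."""
        parent = {top: away}
        pre = [top]
        stack = [top]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    pre.append(v)
                    stack.append(v)
        D: dict = {}
        total = 0
        for u in reversed(pre):
            if u < self.n:
                D[u] = self.masks[u]
                continue
            kids = [v for v in adj[u] if v != parent[u]]
            k1, k2 = kids
            inter = D[k1] & D[k2]
            empty = inter == 0
            total += int(self.weights[empty].sum())
            D[u] = np.where(empty, D[k1] | D[k2], inter)
        return D[top], total, set(pre)


# ---------------------------------------------------------------------------
# heuristics


def _distinctness_order(core: _Core, rng: random.Random) -> list:
    """Taxa sorted so that early placements are mutually most different,
    which tightens branch-and-bound lower bounds early."""
    n = core.n
    masks, w = core.masks, core.weights

    def dist(i: int, j: int) -> int:
        return int(w[(masks[i] & masks[j]) == 0].sum())

    best_pair, best_d = (0, 1), -1
    for i, j in itertools.combinations(range(n), 2):
        d = dist(i, j)
        if d > best_d:
            best_pair, best_d = (i, j), d
    order = list(best_pair)
    placed_or = masks[order[0]] | masks[order[1]]
    remaining = [i for i in range(n) if i not in order]
    while remaining:
        scores = [
            int(w[(masks[i] & placed_or) == 0].sum()) for i in remaining
        ]
        top = max(scores)
        pick = rng.choice(
            [i for i, s in zip(remaining, scores) if s == top]
        )
        order.append(pick)
        placed_or = placed_or | masks[pick]
        remaining.remove(pick)
    return order


def _stepwise(core: _Core, order: list, rng: random.Random) -> dict:
    adj = core.star(order[0], order[1], order[2])
    next_internal = core.n + 1
    for leaf in order[3:]:
        L, edges, costs = core.insertion_costs(adj, core.masks[leaf])
        best = min(costs)
        choices = [e for e, c in zip(edges, costs) if c == best]
        edge = choices[rng.randrange(len(choices))] if len(choices) > 1 else choices[0]
        core.insert(adj, leaf, edge, next_internal)
        next_internal += 1
    return adj


def stepwise_addition(
    matrix: CharacterMatrix,
    order: list | None = None,
    seed: int | None = None,
) -> Cladogram:
    """Greedy stepwise addition: each taxon joins the edge where it adds
    the fewest steps; ties broken by the seeded RNG."""
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    core = _Core(matrix)
    rng = random.Random(seed)
    if order is None:
        idx = list(range(core.n))
        rng.shuffle(idx)
    else:
        lookup = {t: i for i, t in enumerate(core.taxa)}
        idx = [lookup[t] if isinstance(t, str) else t for t in order]
        if sorted(idx) != list(range(core.n)):
            raise ValueError("order must be a permutation of the taxa")
    adj = _stepwise(core, idx, rng)
    return core.to_cladogram(adj)


# -- branch swapping --------------------------------------------------------


def _nni_moves(adj: dict, n_leaves: int):
    """The 2(n-3) distinct NNI rearrangements of a binary tree.

    For each internal edge (u,v), exchanging one fixed u-side subtree
    with each of the two v-side subtrees gives the two alternative
    resolutions of that edge.
    """
    internal_edges = [
        (u, v)
        for u in adj
        if u >= n_leaves
        for v in adj[u]
        if v >= n_leaves and u < v
    ]
    for u, v in internal_edges:
        a = [x for x in adj[u] if x != v][0]
        for b in [x for x in adj[v] if x != u]:
            yield (u, a, v, b)


def _swap_subtrees(adj: dict, u: int, a: int, v: int, b: int) -> None:
    """Exchange subtree a (attached at u) with subtree b (attached at v)."""
    adj[u] = [x if x != a else b for x in adj[u]]
    adj[v] = [x if x != b else a for x in adj[v]]
    adj[a] = [x if x != u else v for x in adj[a]]
    adj[b] = [x if x != v else u for x in adj[b]]


def _spr_improve(core: _Core, adj: dict, L: int):
    """Best-improvement SPR sweep; returns (found, new_L)."""
    n = core.n
    best = (0, None)  # (improvement, action)
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    for away, top in [(u, v) for (u, v) in edges] + [
        (v, u) for (u, v) in edges
    ]:
        # prune the component containing `top` (cut edge away-top);
        # `away` must remain in a tree with >= 3 leaves
        if away < n:
            continue  # pruning "all but one leaf" is never useful
        x_mask, L_sub, sub_nodes = core.subtree_down(adj, away, top)
        n_sub_leaves = sum(1 for s in sub_nodes if s < n)
        if n - n_sub_leaves < 3:
            continue
        # detach
        rest = [x for x in adj[away] if x != top]
        p, q = rest
        adj[p] = [x if x != away else q for x in adj[p]]
        adj[q] = [x if x != away else p for x in adj[q]]
        saved_away = adj.pop(away)
        L_red, redges, costs = core.insertion_costs(
            adj, x_mask, exclude=sub_nodes
        )
        for e, c in zip(redges, costs):
            cand = L_red + L_sub + c
            if L - cand > best[0]:
                best = (L - cand, (away, top, p, q, e, saved_away))
        # reattach at original position
        adj[away] = saved_away
        adj[p] = [x if x != q else away for x in adj[p]]
        adj[q] = [x if x != p else away for x in adj[q]]
    if best[1] is None:
        return False, L
    away, top, p, q, (eu, ev), saved_away = best[1]
    adj[p] = [x if x != away else q for x in adj[p]]
    adj[q] = [x if x != away else p for x in adj[q]]
    adj[away] = [top, eu, ev]
    adj[eu] = [x if x != ev else away for x in adj[eu]]
    adj[ev] = [x if x != eu else away for x in adj[ev]]
    return True, L - best[0]


def branch_swap(
    tree: Cladogram,
    matrix: CharacterMatrix,
    move: str = "tbr",
    seed: int | None = None,
) -> Cladogram:
    """Hill-climb from ``tree`` with the chosen neighborhood until no
    neighbor is shorter; the result never scores worse than the input."""
    core = _Core(matrix)
    adj = core.from_cladogram(tree)
    adj, _ = _swap_adj(core, adj, move, random.Random(seed))
    return core.to_cladogram(adj)


def _swap_adj(core: _Core, adj: dict, move: str, rng: random.Random):
    if move not in ("nni", "spr", "tbr"):
        raise ValueError(f"unknown move {move!r}")
    L = core.score(adj)
    improved = True
    while improved:
        improved = False
        if move == "nni":
            for u, a, v, b in list(_nni_moves(adj, core.n)):
                _swap_subtrees(adj, u, a, v, b)
                L2 = core.score(adj)
                if L2 < L:
                    L = L2
                    improved = True
                    break  # neighborhood is stale after a move
                _swap_subtrees(adj, u, b, v, a)
        elif move == "spr":
            improved, L = _spr_improve(core, adj, L)
        else:  # tbr
            improved, L = _tbr_improve(core, adj, L)
    return adj, L


def _tbr_improve(core: _Core, adj: dict, L: int):
    """First-improvement TBR sweep (bisect + reconnect anywhere)."""
    n = core.n
    internal_edges = [
        (u, v)
        for u in adj
        if u >= n
        for v in adj[u]
        if v >= n and u < v
    ]
    for u, v in internal_edges:
        a1, a2 = (x for x in adj[u] if x != v)
        b1, b2 = (x for x in adj[v] if x != u)
        half1 = _component(adj, u, without=v)
        half2 = _component(adj, v, without=u)
        e1s = [(p, q) for p in half1 for q in adj[p] if q in half1 and p < q]
        e2s = [(p, q) for p in half2 for q in adj[p] if q in half2 and p < q]
        for e1 in e1s:
            for e2 in e2s:
                cand = _tbr_apply(adj, u, v, e1, e2)
                L2 = core.score(cand)
                if L2 < L:
                    adj.clear()
                    adj.update(cand)
                    return True, L2
    return False, L


def _component(adj: dict, start: int, without: int) -> set:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y != without and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _tbr_apply(adj: dict, u: int, v: int, e1: tuple, e2: tuple) -> dict:
    """Tree obtained by cutting edge (u,v) and reconnecting a new edge
    between points subdividing e1 (in u's half) and e2 (in v's half).

    u and v are recycled as the subdividing nodes; returns a fresh
    adjacency dict, the input is left untouched.
    """
    new = {k: list(vs) for k, vs in adj.items()}
    # detach u from v and dissolve both endpoints into their halves
    a1, a2 = (x for x in new[u] if x != v)
    b1, b2 = (x for x in new[v] if x != u)
    new[a1] = [x if x != u else a2 for x in new[a1]]
    new[a2] = [x if x != u else a1 for x in new[a2]]
    new[b1] = [x if x != v else b2 for x in new[b1]]
    new[b2] = [x if x != v else b1 for x in new[b2]]
    # re-subdivide e1 with u, e2 with v, join u-v; an edge that named
    # the dissolved node now runs between that node's two neighbors
    p1, q1 = (a1, a2) if u in e1 else e1
    p2, q2 = (b1, b2) if v in e2 else e2
    new[u] = [p1, q1, v]
    new[p1] = [x if x != q1 else u for x in new[p1]]
    new[q1] = [x if x != p1 else u for x in new[q1]]
    new[v] = [p2, q2, u]
    new[p2] = [x if x != q2 else v for x in new[p2]]
    new[q2] = [x if x != p2 else v for x in new[q2]]
    return new


def heuristic_search(
    matrix: CharacterMatrix,
    starts: int = 10,
    move: str = "tbr",
    seed: int | None = None,
) -> SearchResult:
    """Random-addition stepwise starts + branch swapping; returns the
    set of distinct best trees found across all starts."""
    core = _Core(matrix)
    rng = random.Random(seed)
    best_L = None
    best: dict[str, Cladogram] = {}
    for _ in range(starts):
        order = list(range(core.n))
        rng.shuffle(order)
        adj = _stepwise(core, order, rng)
        adj, L = _swap_adj(core, adj, move, rng)
        if best_L is None or L < best_L:
            best_L = L
            best = {}
        if L == best_L:
            t = core.to_cladogram(adj)
            best[t.to_newick()] = t
    trees = tuple(best[k] for k in sorted(best))
    return SearchResult(trees, best_L, core.evals, exact=False)


# ---------------------------------------------------------------------------
# exact engines


def exhaustive_search(
    matrix: CharacterMatrix, guard: int = EXHAUSTIVE_GUARD
) -> SearchResult:
    """Score every topology; the oracle for the branch-and-bound."""
    if matrix.n_taxa > guard:
        raise ValueError(
            f"{matrix.n_taxa} taxa exceeds exhaustive guard {guard}"
        )
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    core = _Core(matrix)
    best_L = None
    best = {}
    for tree in enumerate_topologies(matrix.taxa, guard=guard):
        L = core.score(core.from_cladogram(tree))
        if best_L is None or L < best_L:
            best_L = L
            best = {}
        if L == best_L:
            best[tree.to_newick()] = tree
    trees = tuple(best[k] for k in sorted(best))
    return SearchResult(trees, best_L, core.evals, exact=True)


def branch_and_bound(
    matrix: CharacterMatrix,
    config: SearchConfig | None = None,
) -> SearchResult:
    """All most-parsimonious trees by implicit enumeration (exact).

    A partial tree on the first k taxa of the addition order is
    extended by inserting taxon k+1 on each edge; the exact insertion
    cost comes from the partial tree's midpoint state sets, and the
    branch is pruned when the new length plus the unplaced-state lower
    bound exceeds the incumbent.  The lower bound counts, per
    character, the states that still must appear (definite states of
    unplaced taxa absent from every placed cell).
    """
    if matrix.n_taxa < 4:
        raise ValueError("branch and bound needs at least 4 taxa")
    config = config or SearchConfig()
    core = _Core(matrix)
    rng = random.Random(config.seed)

    # incumbent from stepwise addition + branch swapping
    incumbent_L = None
    for _ in range(max(1, config.starts)):
        order = list(range(core.n))
        rng.shuffle(order)
        adj = _stepwise(core, order, rng)
        adj, L = _swap_adj(core, adj, config.move, rng)
        if incumbent_L is None or L < incumbent_L:
            incumbent_L = L

    if config.addition_order == "distinctness":
        order = _distinctness_order(core, rng)
    elif config.addition_order == "input":
        order = list(range(core.n))
    elif config.addition_order == "random":
        order = list(range(core.n))
        rng.shuffle(order)
    else:
        raise ValueError(
            f"unknown addition order {config.addition_order!r}"
        )

    n = core.n
    # suffix OR of definite states over the addition order, for bounds
    suffix = np.zeros((n + 1, core.defmasks.shape[1]), dtype=np.uint8)
    for k in range(n - 1, -1, -1):
        suffix[k] = suffix[k + 1] | core.defmasks[order[k]]

    best: dict[str, Cladogram] = {}
    incumbent = incumbent_L
    w = core.weights

    def bound(k: int, placed_or: np.ndarray) -> int:
        need = suffix[k] & ~placed_or
        return int((w * POPCOUNT[need]).sum())

    adj = core.star(order[0], order[1], order[2])
    placed0 = core.masks[order[0]] | core.masks[order[1]] | core.masks[order[2]]

    def descend(k: int, placed_or: np.ndarray) -> None:
        nonlocal incumbent
        leaf = order[k]
        L_here, edges, costs = core.insertion_costs(adj, core.masks[leaf])
        new_placed = placed_or | core.masks[leaf]
        last = k == n - 1
        b = 0 if last else bound(k + 1, new_placed)
        ranked = sorted(zip(costs, range(len(edges))))
        for c, i in ranked:
            total = L_here + c
            if total + b > incumbent:
                break  # costs sorted: the rest prune too
            core.insert(adj, leaf, edges[i], n + k - 1)
            if last:
                if total < incumbent:
                    incumbent = total
                    best.clear()
                if total == incumbent:
                    t = core.to_cladogram(adj)
                    best[t.to_newick()] = t
            else:
                descend(k + 1, new_placed)
            core.remove_leaf(adj, leaf)

    descend(3, placed0)
    trees = tuple(best[key] for key in sorted(best))
    return SearchResult(trees, incumbent, core.evals, exact=True)
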
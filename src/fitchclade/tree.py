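"""Cladograms: unrooted leaf-labeled trees without branch lengths.

Parsimony is a function of topology alone, so trees here carry no
branch lengths and no meaningful root: a :class:`Cladogram` is an
unrooted tree whose internal nodes have degree >= 3 (degree exactly 3
everywhere for binary trees; consensus trees may be multifurcating).
A root enters only as a *view* for reporting — :meth:`Cladogram.rooted`
places the designated outgroup sister to all remaining taxa, which is
how character polarity is read off.

Topology identity is defined by the set of non-trivial bipartitions
(splits); two trees are equal iff they induce the same splits on the
same leaf set.  :func:`write_newick` with ``canonical=True`` serializes
equal topologies to identical text.
"""

from __future__ import annotations

import random as _random
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Cladogram",
    "RootedView",
    "read_newick",
    "write_newick",
    "enumerate_topologies",
    "random_topology",
    "n_unrooted_topologies",
]

ENUMERATION_GUARD = 10


class Cladogram:
    """Unrooted leaf-labeled tree (cladogram).

    Construct via :meth:`from_newick`, :meth:`from_nested`,
    :meth:`from_splits`, or the search/simulation routines.  Instances
    are treated as immutable.
    """

    __slots__ = ("_adj", "_label", "_leaf_of", "outgroup", "_splits_cache")

    def __init__(self, adj: dict, labels: dict, outgroup: str | None = None):
        self._adj = {n: tuple(nb) for n, nb in adj.items()}
        self._label = dict(labels)
        self._leaf_of = {v: k for k, v in labels.items()}
        if len(self._leaf_of) != len(self._label):
            raise ValueError("duplicate leaf labels")
        if outgroup is not None and outgroup not in self._leaf_of:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        self.outgroup = outgroup
        self._splits_cache = None
        self._validate()

    def _validate(self) -> None:
        for n, nbrs in self._adj.items():
            if len(nbrs) != len(set(nbrs)):
                raise ValueError("parallel edges")
            for m in nbrs:
                if n not in self._adj.get(m, ()):
                    raise ValueError("asymmetric adjacency")
        degs = {n: len(nb) for n, nb in self._adj.items()}
        leaves = set(self._label)
        for n, d in degs.items():
            if n in leaves:
                if d > 1:
                    raise ValueError(f"labeled node {n} has degree {d}")
            elif d < 3 and len(self._adj) > 2:
                raise ValueError(f"unlabeled node {n} has degree {d}")
        if len(self._adj) > 1:
            seen = {next(iter(self._adj))}
            stack = list(seen)
            while stack:
                for m in self._adj[stack.pop()]:
                    if m not in seen:
                        seen.add(m)
                        stack.append(m)
            if seen != set(self._adj):
                raise ValueError("tree is not connected")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, outgroup: str | None = None) -> "Cladogram":
        return read_newick(text, outgroup=outgroup)

    @classmethod
    def from_nested(cls, nested, outgroup: str | None = None) -> "Cladogram":
        """Build from nested tuples of labels, e.g. ``(("A","B"),("C","D"))``."""
        adj: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        counter = [0]

        def new_node() -> int:
            counter[0] += 1
            adj[counter[0]] = []
            return counter[0]

        def build(obj) -> int:
            node = new_node()
            if isinstance(obj, str):
                labels[node] = obj
                return node
            for child in obj:
                c = build(child)
                adj[node].append(c)
                adj[c].append(node)
            return node

        root = build(nested)
        _suppress_degree_two(adj, labels, root)
        return cls(adj, labels, outgroup=outgroup)

    @classmethod
    def from_splits(
        cls,
        leaves: Iterable[str],
        splits: Iterable[frozenset],
        outgroup: str | None = None,
    ) -> "Cladogram":
        """Tree containing exactly the given pairwise-compatible splits.

        Splits may be given as either side; internally each is taken as
        the side not containing the reference leaf (the minimum label).
        Raises ``ValueError`` on incompatible splits.
        """
        leaves = sorted(set(leaves))
        if not leaves:
            raise ValueError("no leaves")
        ref = leaves[0]
        clades = []
        for s in splits:
            side = frozenset(s)
            if ref in side:
                side = frozenset(leaves) - side
            if not side or not side < set(leaves):
                raise ValueError(f"split {sorted(s)} not a proper subset")
            if len(side) >= 2 and len(side) <= len(leaves) - 2:
                clades.append(side)
        clades = sorted(set(clades), key=lambda c: (-len(c), sorted(c)))
        for i, a in enumerate(clades):
            for b in clades[i + 1 :]:
                if a & b and not (a <= b or b <= a):
                    raise ValueError(
                        f"incompatible splits {sorted(a)} / {sorted(b)}"
                    )
        adj: dict[int, list[int]] = {0: []}
        labels: dict[int, str] = {}
        counter = [0]
        # nest clades by containment under a star root
        children: dict[int, list] = {0: []}
        clade_node: dict[frozenset, int] = {}
        for c in clades:  # large to small: parent is smallest enclosing
            counter[0] += 1
            node = counter[0]
            adj[node] = []
            parent = 0
            best = None
            for d, pn in clade_node.items():
                if c < d and (best is None or len(d) < len(best)):
                    best, parent = d, pn
            adj[parent].append(node)
            adj[node].append(parent)
            clade_node[c] = node
        for leaf in leaves:
            counter[0] += 1
            node = counter[0]
            labels[node] = leaf
            parent = 0
            best = None
            for d, pn in clade_node.items():
                if leaf in d and (best is None or len(d) < len(best)):
                    best, parent = d, pn
            adj[node] = [parent]
            adj[parent].append(node)
        _suppress_degree_two(adj, labels, 0)
        return cls(adj, labels, outgroup=outgroup)

    # -- accessors -------------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return frozenset(self._leaf_of)

    @property
    def n_leaves(self) -> int:
        return len(self._label)

    @property
    def is_binary(self) -> bool:
        if self.n_leaves < 3:
            return True
        return all(
            len(nb) == 3 for n, nb in self._adj.items() if n not in self._label
        )

    def bipartitions(self) -> frozenset:
        """Non-trivial splits; each reported as the side *not* holding
        the lexicographically smallest leaf label."""
        if self._splits_cache is not None:
            return self._splits_cache
        n = self.n_leaves
        out = set()
        if n >= 4:
            ref = min(self._leaf_of)
            for parent, child, clade in self._clades_from(self._leaf_of[ref]):
                if 2 <= len(clade) <= n - 2:
                    out.add(frozenset(clade))
        self._splits_cache = frozenset(out)
        return self._splits_cache

    def _clades_from(self, root_leaf: int):
        """Yield (parent, child, leafset-below-child) away from root_leaf."""
        order = []
        parent = {root_leaf: None}
        stack = [root_leaf]
        while stack:
            u = stack.pop()
            order.append(u)
            for v in self._adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    stack.append(v)
        below: dict[int, set] = {}
        for u in reversed(order):
            if u in self._label:
                below[u] = {self._label[u]}
            else:
                below[u] = set()
            for v in self._adj[u]:
                if parent.get(v) == u:
                    below[u] |= below[v]
        for u in order:
            if parent[u] is not None:
                yield parent[u], u, below[u]

    def rooted(self, outgroup: str | None = None) -> "RootedView":
        """Rooted view with ``outgroup`` sister to all remaining taxa."""
        og = outgroup or self.outgroup
        if og is None:
            raise ValueError("no outgroup designated")
        if og not in self._leaf_of:
            raise ValueError(f"outgroup {og!r} is not a leaf of this tree")
        og_node = self._leaf_of[og]
        children: dict[int, tuple] = {}
        root = ("root",)  # unique sentinel id
        if self.n_leaves == 1:
            return RootedView(root, {root: (og_node,), og_node: ()},
                              dict(self._label), og)
        attach = self._adj[og_node][0]
        # parent[attach] = og_node so the outgroup leaf is excluded
        # from attach's children; conceptually both hang off the root
        parent = {og_node: root, attach: og_node}
        children[root] = (og_node, attach)
        stack = [attach]
        while stack:
            u = stack.pop()
            kids = tuple(v for v in self._adj[u] if v != parent[u])
            children[u] = kids
            for v in kids:
                parent[v] = u
                stack.append(v)
        return RootedView(root, children, dict(self._label), og)

    def reroot(self, outgroup: str) -> "Cladogram":
        """Same unrooted topology with ``outgroup`` designated for rooting."""
        if outgroup not in self._leaf_of:
            raise ValueError(f"unknown outgroup label {outgroup!r}")
        return Cladogram(self._adj, self._label, outgroup=outgroup)

    # -- identity --------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cladogram):
            return NotImplemented
        return (
            self.leaves == other.leaves
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self):
        return hash((self.leaves, self.bipartitions()))

    def __repr__(self) -> str:
        return f"<Cladogram {self.n_leaves} leaves>"

    def to_newick(self, canonical: bool = True) -> str:
        return write_newick(self, canonical=canonical)


@dataclass(frozen=True)
class RootedView:
    """Rooted traversal of a cladogram (no extra topology information)."""

    root: object
    children: dict
    labels: dict
    outgroup: str

    def postorder(self) -> list:
        order, stack = [], [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self.children.get(u, ()))
        order.reverse()
        return order

    def clades(self) -> dict:
        """node -> frozenset of leaf labels below it."""
        out: dict = {}
        for u in self.postorder():
            kids = self.children.get(u, ())
            if not kids:
                out[u] = frozenset((self.labels[u],))
            else:
                s = frozenset()
                for v in kids:
                    s |= out[v]
                out[u] = s
        return out

    def branches(self) -> Iterator[tuple]:
        """(parent, child) pairs, root excluded as a child."""
        for u, kids in self.children.items():
            for v in kids:
                yield (u, v)


# ---------------------------------------------------------------------------
# Newick I/O


def _suppress_degree_two(adj: dict, labels: dict, start) -> None:
    for n in list(adj):
        if n not in labels and len(adj[n]) == 2:
            a, b = adj[n]
            adj[a] = [x if x != n else b for x in adj[a]]
            adj[b] = [x if x != n else a for x in adj[b]]
            del adj[n]


_TOKEN = re.compile(r"\s*(\(|\)|,|;|'(?:[^']|'')*'|[^\s(),;]+)")


def read_newick(text: str, outgroup: str | None = None) -> Cladogram:
    """Parse a single Newick tree into an (unrooted) cladogram.

    Branch lengths (``:x``) are accepted and discarded; a rooted
    two-child representation is unrooted by suppressing the root.
    """
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise ValueError(f"bad newick near {text[pos:pos+20]!r}")
        tokens.append(m.group(1))
        pos = m.end()
        if m.group(1) == ";":
            break
    if not tokens or tokens[-1] != ";":
        raise ValueError("newick text not terminated by ';'")
    tokens.pop()

    def clean(tok: str) -> str:
        if tok.startswith("'") and tok.endswith("'"):
            return tok[1:-1].replace("''", "'")
        return tok.split(":")[0].replace("_", " ")

    idx = [0]

    def parse():
        if tokens[idx[0]] == "(":
            idx[0] += 1
            kids = [parse()]
            while tokens[idx[0]] == ",":
                idx[0] += 1
                kids.append(parse())
            if tokens[idx[0]] != ")":
                raise ValueError("unbalanced parentheses in newick")
            idx[0] += 1
            # optional internal label / branch length: skip
            if idx[0] < len(tokens) and tokens[idx[0]] not in "(),":
                idx[0] += 1
            return tuple(kids)
        tok = tokens[idx[0]]
        if tok in "),":
            raise ValueError("empty clade in newick")
        idx[0] += 1
        label = clean(tok)
        if not label:
            raise ValueError("empty leaf label")
        return label

    try:
        nested = parse()
    except IndexError:
        raise ValueError("unbalanced parentheses in newick") from None
    if idx[0] != len(tokens):
        raise ValueError("trailing tokens after newick tree")
    return Cladogram.from_nested(nested, outgroup=outgroup)


def _nwk_label(label: str) -> str:
    if re.fullmatch(r"[\w.|-]+", label) and " " not in label:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Cladogram, canonical: bool = True) -> str:
    """Serialize; with ``canonical=True`` equal topologies give equal text.

    Canonical form roots the tree on its lexicographically smallest
    leaf and sorts children by their smallest descendant label, so the
    text is a total order key on topologies.
    """
    if tree.n_leaves == 0:
        raise ValueError("empty tree")
    if tree.n_leaves == 1:
        return _nwk_label(next(iter(tree.leaves))) + ";"
    if canonical or tree.outgroup is None:
        top_label = min(tree.leaves)
    else:
        top_label = tree.outgroup
    top = tree._leaf_of[top_label]
    attach = tree._adj[top][0]

    def serialize(u, parent):
        if u in tree._label:
            return (tree._label[u], _nwk_label(tree._label[u]))
        parts = [serialize(v, u) for v in tree._adj[u] if v != parent]
        if canonical:
            parts.sort(key=lambda p: p[0])
        return (
            min(p[0] for p in parts),
            "(" + ",".join(p[1] for p in parts) + ")",
        )

    if tree.n_leaves == 2:
        other = serialize(attach, top)
        return f"({_nwk_label(top_label)},{other[1]});"
    _, inner = serialize(attach, top)
    return f"({_nwk_label(top_label)},{','.join(_split_top(inner))});"


def _split_top(inner: str) -> list:
    """Split '(a,b,c)' into top-level parts [a, b, c]."""
    depth = 0
    parts, cur = [], []
    for ch in inner[1:-1]:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


# ---------------------------------------------------------------------------
# enumeration and random generation


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n >= 3 leaves."""
    if n < 3:
        return 1
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def _edge_list_to_cladogram(
    edges: Sequence[tuple], labels: dict, outgroup: str | None = None
) -> Cladogram:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return Cladogram(adj, labels, outgroup=outgroup)


def enumerate_topologies(
    leaves: Sequence[str], guard: int = ENUMERATION_GUARD
) -> Iterator[Cladogram]:
    """Every unrooted binary topology on ``leaves``, each exactly once.

    Exhaustive edge-insertion enumeration; refuses more than ``guard``
    leaves because the count grows as (2n-5)!!.
    """
    labels = list(leaves)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 leaves")
    if n > guard:
        raise ValueError(
            f"{n} leaves exceeds enumeration guard {guard} "
            f"({n_unrooted_topologies(n)} topologies)"
        )
    label_map = {i: lab for i, lab in enumerate(labels)}
    first_internal = n

    def recurse(edges: list, k: int, next_internal: int):
        if k == n:
            yield _edge_list_to_cladogram(edges, label_map)
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            rest = edges[:i] + edges[i + 1 :]
            new_edges = rest + [(u, w), (w, v), (w, k)]
            yield from recurse(new_edges, k + 1, next_internal + 1)

    start = [(0, first_internal), (1, first_internal), (2, first_internal)]
    yield from recurse(start, 3, first_internal + 1)


def random_topology(
    leaves: Sequence[str],
    seed: int | None = None,
    rng: _random.Random | None = None,
) -> Cladogram:
    """Uniform random unrooted binary topology via sequential addition.

    Leaves are attached in order to a uniformly chosen existing edge;
    with the insertion order fixed, every topology arises from exactly
    one choice sequence, so the draw is uniform over all (2n-5)!!
    topologies.
    """
    labels = list(leaves)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 leaves")
    if rng is None:
        rng = _random.Random(seed)
    label_map = {i: lab for i, lab in enumerate(labels)}
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for k in range(3, n):
        i = rng.randrange(len(edges))
        u, v = edges.pop(i)
        w = next_internal
        next_internal += 1
        edges += [(u, w), (w, v), (w, k)]
    return _edge_list_to_cladogram(edges, label_map)
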
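"""Jackknife clade support by character resampling, and consensus trees.

Each pseudoreplicate deletes every character independently with a
fixed probability (0.36 in the study, the classic e^-1-like removal
rate), re-searches the reduced matrix heuristically, and contributes
the splits of the strict consensus of its best trees.  A clade's
support is the percentage of replicates whose consensus contains it
("absolute frequency").  Replicates are driven by per-replicate
substreams of one master seed, so any single replicate can be
reproduced in isolation and whole runs are bit-for-bit repeatable.
"""

from __future__ import annotations

import functools
import logging
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .matrix import CharacterMatrix
from .search import heuristic_search
from .tree import Cladogram

__all__ = [
    "JackknifeConfig",
    "SupportTable",
    "jackknife_matrix",
    "jackknife_support",
    "strict_consensus",
    "majority_consensus",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JackknifeConfig:
    """Resampling configuration.

    ``p_remove`` is the independent per-character deletion
    probability; ``starts``/``move`` parameterize the per-replicate
    heuristic search; ``support_floor`` is the reporting threshold
    (values below it are conventionally not drawn on trees).
    """

    p_remove: float = 0.36
    replicates: int = 2000
    seed: int | None = None
    starts: int = 5
    move: str = "spr"
    support_floor: float = 50.0

    def __post_init__(self):
        if not 0.0 <= self.p_remove <= 1.0:
            raise ValueError("p_remove must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class SupportTable:
    """Split -> jackknife percentage over the full taxon set."""

    taxa: tuple
    entries: dict  # frozenset split -> float percent
    config: JackknifeConfig

    def support_of(self, clade: Iterable[str]) -> float:
        """Support for a clade given as either side of its split."""
        side = frozenset(clade)
        if side in self.entries:
            return self.entries[side]
        other = frozenset(self.taxa) - side
        return self.entries.get(other, 0.0)

    def filtered(self, floor: float | None = None) -> dict:
        floor = self.config.support_floor if floor is None else floor
        return {s: v for s, v in self.entries.items() if v >= floor}

    def to_tsv(self, floor: float = 0.0) -> str:
        lines = ["support\tclade"]
        for s, v in sorted(
            self.entries.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        ):
            if v >= floor:
                lines.append(f"{v:.1f}\t{','.join(sorted(s))}")
        return "\n".join(lines) + "\n"

    def annotated_newick(self, tree: Cladogram, floor: float = 0.0) -> str:
        """Canonical Newick of ``tree`` with support values attached as
        internal node labels (clades below ``floor`` left blank)."""
        return _annotate(tree, self, floor)


def _annotate(tree: Cladogram, table: SupportTable, floor: float) -> str:
    from .tree import _nwk_label

    top_label = min(tree.leaves)
    top = tree._leaf_of[top_label]
    attach = tree._adj[top][0]

    def serialize(u, parent):
        if u in tree._label:
            return (tree._label[u], _nwk_label(tree._label[u]), frozenset(
                (tree._label[u],)
            ))
        parts = [serialize(v, u) for v in tree._adj[u] if v != parent]
        parts.sort(key=lambda p: p[0])
        leafset = frozenset().union(*(p[2] for p in parts))
        sup = table.support_of(leafset)
        label = f"{sup:.0f}" if sup >= floor and sup > 0 else ""
        return (
            min(p[0] for p in parts),
            "(" + ",".join(p[1] for p in parts) + ")" + label,
            leafset,
        )

    from .tree import _split_top

    _, inner, _ = serialize(attach, top)
    bare = inner[: inner.rindex(")") + 1] if inner.endswith(")") else inner
    # top-level: (top, children-of-attach...)
    parts = _split_top(bare)
    return f"({_nwk_label(top_label)},{','.join(parts)});"


def jackknife_matrix(
    matrix: CharacterMatrix, p_remove: float, rng: random.Random
) -> CharacterMatrix:
    """One pseudoreplicate: delete each character independently with
    probability ``p_remove``; taxa are untouched.  A draw deleting all
    characters is degenerate and is redrawn (logged)."""
    if not 0.0 <= p_remove <= 1.0:
        raise ValueError("p_remove must be in [0, 1]")
    while True:
        keep = [
            i
            for i in range(1, matrix.n_char + 1)
            if rng.random() >= p_remove
        ]
        if keep:
            return matrix.subset(chars=keep)
        if p_remove >= 1.0:
            # deletion certain: an empty replicate is the only outcome
            return matrix.subset(chars=[])
        log.info("jackknife replicate drew 0 characters; redrawing")


def jackknife_support(
    matrix: CharacterMatrix,
    config: JackknifeConfig | None = None,
    progress: bool = False,
) -> SupportTable:
    """Jackknife support for every split over the full taxon set.

    Per replicate, ``config.starts`` random-addition stepwise trees
    are refined by branch swapping; the splits common to all best
    trees found (the replicate's strict consensus) count once each.
    """
    config = config or JackknifeConfig()
    counts: dict = {}
    n = config.replicates
    for i in range(n):
        rng = random.Random(f"{config.seed}:jk:{i}")
        rep = jackknife_matrix(matrix, config.p_remove, rng)
        if rep.n_char == 0:
            continue  # p_remove == 1: nothing supports anything
        res = heuristic_search(
            rep,
            starts=config.starts,
            move=config.move,
            seed=rng.randrange(2**31),
        )
        splits = _common_splits(res.optimal_trees)
        for s in splits:
            counts[s] = counts.get(s, 0) + 1
        if progress and (i + 1) % 200 == 0:
            log.info("jackknife: %d/%d replicates", i + 1, n)
    entries = {s: 100.0 * c / n for s, c in counts.items()}
    return SupportTable(taxa=matrix.taxa, entries=entries, config=config)


def _common_splits(trees: Sequence[Cladogram]) -> frozenset:
    return functools.reduce(
        lambda a, b: a & b, (t.bipartitions() for t in trees)
    )


def strict_consensus(trees: Sequence[Cladogram]) -> Cladogram:
    """Tree containing exactly the splits present in every input tree."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree set")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            raise ValueError("consensus requires a common leaf set")
    og = trees[0].outgroup
    return Cladogram.from_splits(leaves, _common_splits(trees), outgroup=og)


def majority_consensus(
    trees: Sequence[Cladogram], threshold: float = 0.5
) -> Cladogram:
    """Tree of splits occurring in more than ``threshold`` of inputs.

    For ``threshold >= 0.5`` such splits are pairwise compatible, so
    the tree always exists; ``threshold = 1.0`` reduces to the strict
    consensus.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree set")
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 may give incompatible splits")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            raise ValueError("consensus requires a common leaf set")
    counts: dict = {}
    for t in trees:
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    cut = threshold * len(trees)
    if threshold >= 1.0:
        keep = [s for s, c in counts.items() if c == len(trees)]
    else:
        keep = [s for s, c in counts.items() if c > cut]
    og = trees[0].outgroup
    return Cladogram.from_splits(leaves, keep, outgroup=og)
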
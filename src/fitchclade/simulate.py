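"""Synthetic character matrices with known true trees.

The generator emulates the shape of small morphological data sets
(tens of taxa, tens of unordered binary/ternary characters, an
all-plesiomorphic outgroup, optionally one fragmentary taxon with a
block of missing cells) while controlling the amount of homoplasy:

* ``clean`` regime — every character changes exactly once, on one
  internal branch of the true tree, so the matrix fits the tree
  perfectly (CI = RI = 1) and an exact search must recover the true
  topology uniquely once every internal branch is marked.
* ``mk`` regime — each character receives k >= 1 changes
  (k - 1 Poisson-distributed) on uniformly chosen branches, applied
  root-to-tip so later changes overwrite earlier ones inside their
  subtree; repeated and reversing changes create homoplasy at a rate
  tuned by ``mean_changes``.

Change counts rather than rates-on-branch-lengths are used because
the targets are cladograms: parsimony sees only where changes fall,
not how long branches are.  Defaults mirror the study's data shape
(20 taxa, 40 characters, up to 3 states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .tree import random_topology

__all__ = ["SimulationConfig", "simulate", "inject_missing"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated data set.

    ``missing`` maps taxon labels to the fraction of their cells to
    blank out (e.g. ``{"taxon05": 11/40}`` reproduces the study's one
    fragmentary taxon).  The seed fixes everything: tree, character
    placements, derived states, and missing-cell positions.
    """

    n_taxa: int = 20
    n_char: int = 40
    n_states: int = 3
    regime: str = "clean"  # clean | mk
    mean_changes: float = 1.5
    missing: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.n_char < 1:
            raise ValueError("need at least 1 character")
        if self.n_states not in (2, 3):
            raise ValueError("state alphabet must have 2 or 3 states")
        if self.regime not in ("clean", "mk"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "mk" and self.mean_changes < 1:
            raise ValueError("mean_changes must be >= 1")
        for t, f in self.missing.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"missing fraction for {t!r} not in [0,1]")

    @property
    def taxa(self) -> tuple:
        return ("outgroup",) + tuple(
            f"taxon{i:02d}" for i in range(1, self.n_taxa)
        )


def simulate(config: SimulationConfig) -> tuple:
    """Draw (true_tree, matrix) under ``config``.

    The outgroup keeps the ancestral state 0 for every character, so
    rooting the true tree on it polarizes all characters correctly.
    In the clean regime the first ``n_taxa - 3`` characters cover
    every internal branch once (shuffled), extras land uniformly, so
    any ``n_char >= n_taxa - 3`` guarantees full branch coverage.
    """
    rng = np.random.default_rng(config.seed)
    taxa = config.taxa
    outgroup = taxa[0]
    tree = random_topology(
        taxa, seed=int(rng.integers(2**31))
    ).reroot(outgroup)
    view = tree.rooted(outgroup)
    clades = view.clades()
    n = config.n_taxa

    # branches eligible for changes: everything below the ingroup stem
    all_branches = [
        v
        for _, v in view.branches()
        if clades[v] != tree.leaves and outgroup not in clades[v]
    ]
    internal = [v for v in all_branches if 2 <= len(clades[v]) <= n - 2]

    states_per_taxon = {t: [] for t in taxa}
    if config.regime == "clean":
        cover = list(internal)
        rng.shuffle(cover)
        for i in range(config.n_char):
            if i < len(cover):
                v = cover[i]
            else:
                v = internal[int(rng.integers(len(internal)))]
            derived = int(rng.integers(1, config.n_states))
            members = clades[v]
            for t in taxa:
                states_per_taxon[t].append(derived if t in members else 0)
    else:  # mk
        preorder = view.postorder()[::-1]
        parent = {}
        for u, v in view.branches():
            parent[v] = u
        for _ in range(config.n_char):
            k = 1 + int(rng.poisson(config.mean_changes - 1.0))
            hit = {}
            for _ in range(k):
                v = all_branches[int(rng.integers(len(all_branches)))]
                hit[v] = hit.get(v, 0) + 1
            state = {view.root: 0}
            for u in preorder:
                if u is view.root:
                    continue
                s = state[parent[u]]
                for _ in range(hit.get(u, 0)):
                    others = [
                        x for x in range(config.n_states) if x != s
                    ]
                    s = int(others[int(rng.integers(len(others)))])
                state[u] = s
            for v, lab in view.labels.items():
                states_per_taxon[lab].append(state[v])

    matrix = CharacterMatrix(
        taxa, [states_per_taxon[t] for t in taxa]
    )
    for t, f in config.missing.items():
        matrix = inject_missing(
            matrix, t, f, seed=int(rng.integers(2**31))
        )
    return tree, matrix


def inject_missing(
    matrix: CharacterMatrix,
    taxon: str,
    fraction: float,
    seed: int | None = None,
) -> CharacterMatrix:
    """Blank out ``round(fraction * n_char)`` cells of one taxon at
    seeded uniform positions."""
    if taxon not in matrix.taxa:
        raise KeyError(f"unknown taxon {taxon!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    k = round(fraction * matrix.n_char)
    if k == 0:
        return matrix
    rng = np.random.default_rng(seed)
    hit = set(
        int(i) for i in rng.choice(matrix.n_char, size=k, replace=False)
    )
    rows = []
    for t in matrix.taxa:
        row = list(matrix.row(t))
        if t == taxon:
            row = [
                MISSING if j in hit else c for j, c in enumerate(row)
            ]
        rows.append(row)
    return CharacterMatrix(matrix.taxa, rows, matrix.char_meta)
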
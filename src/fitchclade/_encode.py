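"""Bitmask encoding of character matrices for fast Fitch passes.

Each cell becomes a uint8 bitmask (bit ``s`` = state ``s`` allowed):
a definite state is a single bit, a polymorphic cell the union of its
bits, and MISSING the union of all states observed in that column (a
missing leaf may take any state, so it never forces a change).
"""

from __future__ import annotations

import numpy as np

from .matrix import MISSING, CharacterMatrix


def encode_matrix(
    matrix: CharacterMatrix, taxa_order: tuple | None = None
) -> np.ndarray:
    """(n_taxa, n_char) uint8 bitmask array, rows in ``taxa_order``."""
    taxa = taxa_order if taxa_order is not None else matrix.taxa
    n, c = len(taxa), matrix.n_char
    masks = np.zeros((n, c), dtype=np.uint8)
    col_union = np.zeros(c, dtype=np.uint8)
    rows = [matrix.row(t) for t in taxa]
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell is not MISSING:
                m = 0
                for s in cell:
                    if s > 7:
                        raise ValueError(
                            f"state code {s} exceeds the 8-state encoding"
                        )
                    m |= 1 << s
                masks[i, j] = m
                col_union[j] |= m
    col_union[col_union == 0] = 1  # all-missing column: inert constant
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell is MISSING:
                masks[i, j] = col_union[j]
    return masks


def definite_state_masks(
    matrix: CharacterMatrix, taxa_order: tuple | None = None
) -> np.ndarray:
    """Like :func:`encode_matrix` but MISSING/polymorphic cells are 0.

    Used for admissible search lower bounds: only a single-state cell
    *requires* its state to occur somewhere on the tree.
    """
    taxa = taxa_order if taxa_order is not None else matrix.taxa
    masks = np.zeros((len(taxa), matrix.n_char), dtype=np.uint8)
    for i, t in enumerate(taxa):
        for j, cell in enumerate(matrix.row(t)):
            if cell is not MISSING and len(cell) == 1:
                masks[i, j] = 1 << next(iter(cell))
    return masks


def dedupe_columns(masks: np.ndarray, weights: np.ndarray | None = None):
    """Merge identical columns; returns (unique_masks, weights)."""
    if weights is None:
        weights = np.ones(masks.shape[1], dtype=np.int64)
    uniq, inverse = np.unique(masks, axis=1, return_inverse=True)
    w = np.zeros(uniq.shape[1], dtype=np.int64)
    np.add.at(w, inverse.ravel(), weights)
    return uniq, w


POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)
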
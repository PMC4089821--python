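"""Packaged study data: the 20-taxon x 40-character matrix.

The matrix codes 40 unordered morphological characters (head, thorax,
abdomen, legs, genitalia, body size; states 0/1/2, "?" unknown) for 16
ingroup species of the African platynotine genera *Ectateus* and
*Selinus* plus four outgroup taxa.  *Zidalus latipes* is the most
distant outgroup used to polarize characters.  *Ectateus curtulus* is
known from a single female holotype, hence its 11 missing cells.
"""

from __future__ import annotations

import hashlib

from .matrix import CharacterMatrix

__all__ = [
    "load_fixture",
    "OUTGROUP",
    "OUTGROUP_TAXA",
    "NAMED_CLADES",
    "FIXTURE_SHA256",
]

#: Most distant outgroup; the tree is rooted on it for reporting.
OUTGROUP = "Zidalus latipes"

OUTGROUP_TAXA = (
    "Zidalus latipes",
    "Lechius abacoides",
    "Pseudoselinus punctatostriatus",
    "Upembarus upembaensis",
)

# Rows are stored in the original 8 x 5 block layout; blocks carry no
# meaning and are concatenated on load.
_FIXTURE_ROWS = [
    ("Zidalus latipes", "00000 00000 01000 10000 00000 00100 00000 00000"),
    ("Lechius abacoides", "00000 10000 01000 00000 00000 00000 00000 00000"),
    ("Pseudoselinus punctatostriatus", "00000 01000 01000 00101 00000 01100 00000 00000"),
    ("Upembarus upembaensis", "00000 01000 01000 00100 00000 00100 00000 00000"),
    ("Ectateus crenatus", "00111 00110 10211 10011 11100 00001 00100 10001"),
    ("Ectateus curtulus", "0?010 00100 10211 00011 10100 00??? ????? ??000"),
    ("Ectateus ghesquierei", "00111 00110 10211 00011 11100 00001 00100 10001"),
    ("Ectateus laevistriatus", "01001 10000 00101 10001 00000 10110 01011 01100"),
    ("Ectateus lamottei", "01001 10000 00101 00001 00000 10110 01011 01100"),
    ("Ectateus modestus", "01111 00110 10211 10011 10100 00001 00100 10000"),
    ("Ectateus ursynowiensis", "10000 00000 00100 01000 00101 00001 00100 00000"),
    ("Ectateus villiersi", "10000 00001 00100 01000 00001 00001 00100 00000"),
    ("Selinus calcaripes", "01111 00110 10211 10011 10000 00001 00100 10000"),
    ("Selinus convexipennis", "01001 10000 00101 00001 00000 10110 01010 01100"),
    ("Selinus gravis", "01000 10000 00100 00001 00000 10110 01010 01100"),
    ("Selinus malaisei", "01000 10000 00100 00000 00010 10110 11010 02100"),
    ("Selinus medius", "01000 10000 00100 00000 00010 10110 11010 02100"),
    ("Selinus planus", "01000 10001 00100 00001 00000 01100 00010 00010"),
    ("Selinus plicicollis", "01000 10000 00100 00000 00010 10110 11010 02100"),
    ("Selinus striatus", "01000 10001 00100 00001 00000 01100 00010 00010"),
]

#: SHA-256 of the normalized fixture (taxon<TAB>states per line);
#: guards against accidental edits of the packaged data.
FIXTURE_SHA256 = (
    "7ee143a996155d6b9cbae38ab2a1534a3baef1579d2af53e2c66110a440356a4"
)

_CHAR_DESCRIPTIONS = {
    1: "antenna robust, shorter than pronotum",
    2: "antennomeres 7-11 elongated",
    3: "circular depressions on clypeus/genae present",
    4: "fronto-clypeal suture coarse",
    5: "frons/clypeus lateral indentation deep",
    6: "anterior tentorial pit deep",
    7: "anterior part of mentum elongated",
    8: "anterior pronotal angles curved outwards",
    9: "lateral pronotal sides sinusoidal",
    10: "pronotum widest at the base",
    11: "pronotal margins strongly erected upwards",
    12: "prothorax width / pronotal disc height ratio",
    13: "apophyseal depressions (0 absent, 1 trapezoidal, 2 rounded)",
    14: "pronotal base narrower than elytral base",
    15: "posterior pronotal angles protruding towards elytra",
    16: "pronotal disc punctures coarse",
    17: "prosternal intercoxal process bellied",
    18: "prosternal intercoxal process widened at apex",
    19: "scutellum impressed",
    20: "elytral surface shiny",
    21: "elytral intervals with transverse sculpture",
    22: "elytral intervals strongly convex",
    23: "elytral striae impressed near conspicuous punctures",
    24: "elytral basal margins subparallel",
    25: "metaventrite with coarse longitudinal depression",
    26: "5th abdominal ventrite strongly widened",
    27: "5th abdominal ventrite bordered",
    28: "male protarsi widened",
    29: "female protarsi widened",
    30: "male profemora slender (L/W 4.0-5.6)",
    31: "male mesotibial denticle large",
    32: "penis wide (>= 4x wider than clavae)",
    33: "clavae curved, hook-shaped",
    34: "clavae long (> half paramere length)",
    35: "parameres strongly extended apically",
    36: "parameres narrowest at mid-length",
    37: "paramere apex fusion (0 free, 1 fused, 2 fused+emarginate)",
    38: "bursa copulatrix with 2 additional sacs",
    39: "paraproct longer than coxites",
    40: "body size small (< 9.0 mm)",
}

#: Named groupings recovered in the study, keyed by their customary
#: names; values are frozensets of taxon labels (clades under rooting
#: on the outgroup).
NAMED_CLADES = {
    "Ectateus+Selinus clade": frozenset(
        t for t, _ in _FIXTURE_ROWS if t not in (
            "Zidalus latipes",
            "Lechius abacoides",
            "Pseudoselinus punctatostriatus",
            "Upembarus upembaensis",
        )
    ),
    "Ectateus clade": frozenset({
        "Ectateus crenatus", "Ectateus curtulus", "Ectateus ghesquierei",
        "Ectateus modestus", "Selinus calcaripes",
        "Ectateus ursynowiensis", "Ectateus villiersi",
    }),
    "Selinus clade": frozenset({
        "Selinus convexipennis", "Selinus gravis", "Ectateus laevistriatus",
        "Ectateus lamottei", "Selinus malaisei", "Selinus medius",
        "Selinus plicicollis", "Selinus planus", "Selinus striatus",
    }),
    "modestus group": frozenset({
        "Ectateus crenatus", "Ectateus curtulus", "Ectateus ghesquierei",
        "Ectateus modestus", "Selinus calcaripes",
    }),
    "modestus core": frozenset({
        "Ectateus crenatus", "Ectateus ghesquierei",
        "Ectateus modestus", "Selinus calcaripes",
    }),
    "ghesquierei+crenatus": frozenset({
        "Ectateus ghesquierei", "Ectateus crenatus",
    }),
    "modestus+calcaripes": frozenset({
        "Ectateus modestus", "Selinus calcaripes",
    }),
    "villiersi group": frozenset({
        "Ectateus ursynowiensis", "Ectateus villiersi",
    }),
    "convexipennis group": frozenset({
        "Selinus convexipennis", "Selinus gravis", "Ectateus laevistriatus",
        "Ectateus lamottei", "Selinus malaisei", "Selinus medius",
        "Selinus plicicollis",
    }),
    "convexipennis core": frozenset({
        "Selinus convexipennis", "Ectateus laevistriatus",
        "Ectateus lamottei", "Selinus malaisei", "Selinus medius",
        "Selinus plicicollis",
    }),
    "malaisei+medius+plicicollis": frozenset({
        "Selinus malaisei", "Selinus medius", "Selinus plicicollis",
    }),
    "convexipennis+laevistriatus+lamottei": frozenset({
        "Selinus convexipennis", "Ectateus laevistriatus",
        "Ectateus lamottei",
    }),
    "planus group": frozenset({
        "Selinus planus", "Selinus striatus",
    }),
}


def _normalized_text() -> str:
    return "\n".join(
        f"{taxon}\t{states.replace(' ', '')}" for taxon, states in _FIXTURE_ROWS
    )


def load_fixture() -> CharacterMatrix:
    """The study's character matrix: 20 taxa x 40 characters.

    Verifies the packaged rows against a frozen SHA-256 digest before
    returning; a corrupted fixture raises ``ValueError`` naming the
    offending row where it can be localized.
    """
    digest = hashlib.sha256(_normalized_text().encode()).hexdigest()
    if digest != FIXTURE_SHA256:
        for taxon, states in _FIXTURE_ROWS:
            compact = states.replace(" ", "")
            if len(compact) != 40 or any(
                c not in "012?" for c in compact
            ):
                raise ValueError(
                    f"fixture integrity failure in row {taxon!r}"
                )
        raise ValueError(
            "fixture integrity failure: checksum mismatch "
            f"({digest[:12]}... != {FIXTURE_SHA256[:12]}...)"
        )
    taxa = [t for t, _ in _FIXTURE_ROWS]
    rows = [s.replace(" ", "") for _, s in _FIXTURE_ROWS]
    return CharacterMatrix(taxa, rows, char_meta=_CHAR_DESCRIPTIONS)
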
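"""Discrete morphological character matrices.

A :class:`CharacterMatrix` is the sole input of a cladistic parsimony
analysis: a taxa-by-characters table of small integer state codes
(``0``, ``1``, ``2`` ...), with ``?`` marking missing/unknown cells.
Characters are unordered (any state may change into any other at unit
cost) and carry no weights.

Cells are stored as frozensets of state codes so that polymorphic cells
(a taxon observed in more than one state) are representable, or as the
module-level :data:`MISSING` sentinel.  Character indices are 1-based in
every public interface, matching the usual "char. 30:1" citation style
of morphological systematics.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "CharacterColumn",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
]


class _Missing:
    """Sentinel for an unknown cell; distinct from every state code."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __reduce__(self):
        return (_Missing, ())


#: Singleton marking a missing ("?") cell.
MISSING = _Missing()


class MatrixParseError(ValueError):
    """Raised on malformed matrix input; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


Cell = frozenset  # frozenset[int] or MISSING


def _normalise_cell(value) -> "Cell | _Missing":
    if value is MISSING or value is None:
        return MISSING
    if isinstance(value, int):
        if value < 0:
            raise ValueError(f"negative state code {value}")
        return frozenset((value,))
    if isinstance(value, str):
        if value in ("?", "-"):
            return MISSING
        if not value.isdigit():
            raise ValueError(f"bad cell string {value!r}")
        return frozenset(int(c) for c in value)
    states = frozenset(int(s) for s in value)
    if not states:
        raise ValueError("empty state set is not a valid cell")
    if any(s < 0 for s in states):
        raise ValueError(f"negative state code in {states}")
    return states


@dataclass(frozen=True)
class CharacterColumn:
    """Profile of one character over the non-missing cells of a matrix."""

    index: int  # 1-based character id
    observed_states: frozenset
    counts: Mapping[int, int]
    n_observed: int

    @property
    def n_states(self) -> int:
        return len(self.observed_states)

    @property
    def is_constant(self) -> bool:
        return len(self.observed_states) <= 1

    @property
    def is_informative(self) -> bool:
        """Parsimony-informative: at least two states each borne by >= 2 taxa."""
        return sum(1 for c in self.counts.values() if c >= 2) >= 2


class CharacterMatrix:
    """Taxa x characters table of unordered discrete states.

    Parameters
    ----------
    taxa
        Ordered, unique, non-empty taxon labels.
    rows
        One row per taxon.  Each row is either a string over
        ``0-9 ?`` (with ``{..}``-bracketed polymorphic groups) or an
        iterable of cells (ints, iterables of ints, or ``MISSING``).
    char_meta
        Optional per-character descriptions, keyed 1-based.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        rows: Sequence,
        char_meta: Mapping[int, str] | None = None,
    ):
        taxa = tuple(str(t) for t in taxa)
        if len(taxa) != len(set(taxa)):
            dupes = sorted({t for t in taxa if list(taxa).count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if any(not t for t in taxa):
            raise ValueError("empty taxon label")
        if len(rows) != len(taxa):
            raise ValueError(
                f"{len(taxa)} taxa but {len(rows)} rows of states"
            )
        parsed = []
        for label, row in zip(taxa, rows):
            if isinstance(row, str):
                cells = tuple(_cells_from_string(row))
            else:
                cells = tuple(_normalise_cell(c) for c in row)
            parsed.append(cells)
        widths = {len(r) for r in parsed}
        if len(widths) > 1:
            raise ValueError(
                f"ragged rows: character counts {sorted(widths)} differ"
            )
        self._taxa = taxa
        self._rows = tuple(parsed)
        self._index = {t: i for i, t in enumerate(taxa)}
        self.char_meta = dict(char_meta) if char_meta else {}

    # -- basic accessors -------------------------------------------------

    @property
    def taxa(self) -> tuple:
        return self._taxa

    @property
    def n_taxa(self) -> int:
        return len(self._taxa)

    @property
    def n_char(self) -> int:
        return len(self._rows[0]) if self._rows else 0

    def row(self, taxon: str) -> tuple:
        return self._rows[self._index[taxon]]

    def cell(self, taxon: str, index: int):
        """Cell for ``taxon`` at 1-based character ``index``.

        Returns an ``int`` for a single-state cell, a frozenset for a
        polymorphic cell, or :data:`MISSING`.
        """
        self._check_index(index)
        c = self._rows[self._index[taxon]][index - 1]
        if c is MISSING:
            return MISSING
        if len(c) == 1:
            return next(iter(c))
        return c

    def cell_set(self, taxon: str, index: int):
        """Raw cell: frozenset of states, or MISSING."""
        self._check_index(index)
        return self._rows[self._index[taxon]][index - 1]

    def missing_count(self, taxon: str) -> int:
        return sum(1 for c in self._rows[self._index[taxon]] if c is MISSING)

    def taxa_with_missing(self) -> tuple:
        return tuple(t for t in self._taxa if self.missing_count(t) > 0)

    def _check_index(self, index: int) -> None:
        if not 1 <= index <= self.n_char:
            raise IndexError(
                f"character index {index} out of range 1..{self.n_char}"
            )

    # -- derived views ---------------------------------------------------

    def column_profile(self, index: int) -> CharacterColumn:
        """State inventory of character ``index`` over non-missing cells."""
        self._check_index(index)
        counts: dict[int, int] = {}
        n_observed = 0
        for row in self._rows:
            c = row[index - 1]
            if c is MISSING:
                continue
            n_observed += 1
            for s in c:
                counts[s] = counts.get(s, 0) + 1
        return CharacterColumn(
            index=index,
            observed_states=frozenset(counts),
            counts=counts,
            n_observed=n_observed,
        )

    def column_cells(self, index: int) -> dict:
        """Mapping taxon -> cell (frozenset or MISSING) for one character."""
        self._check_index(index)
        return {t: row[index - 1] for t, row in zip(self._taxa, self._rows)}

    def subset(
        self,
        taxa: Iterable[str] | None = None,
        chars: Iterable[int] | None = None,
    ) -> "CharacterMatrix":
        """Restriction to given taxa and/or 1-based character indices."""
        keep_taxa = tuple(taxa) if taxa is not None else self._taxa
        for t in keep_taxa:
            if t not in self._index:
                raise KeyError(f"unknown taxon {t!r}")
        keep_chars = (
            tuple(chars) if chars is not None else tuple(range(1, self.n_char + 1))
        )
        for i in keep_chars:
            self._check_index(i)
        rows = [
            tuple(self._rows[self._index[t]][i - 1] for i in keep_chars)
            for t in keep_taxa
        ]
        meta = {
            new + 1: self.char_meta[old]
            for new, old in enumerate(keep_chars)
            if old in self.char_meta
        }
        return CharacterMatrix(keep_taxa, rows, meta)

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self._taxa == other._taxa and self._rows == other._rows

    def __hash__(self):
        return hash((self._taxa, self._rows))

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_char} characters>"


# ---------------------------------------------------------------------------
# state-string scanning shared by all dialects


def _cells_from_string(text: str, line: int | None = None):
    """Parse a contiguous state string like ``0?1{01}2`` into cells."""
    cells = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "?" or ch == "-":
            cells.append(MISSING)
            i += 1
        elif ch.isdigit():
            cells.append(frozenset((int(ch),)))
            i += 1
        elif ch in "{[(":
            close = {"{": "}", "[": "]", "(": ")"}[ch]
            j = text.find(close, i)
            if j < 0:
                raise MatrixParseError(f"unterminated group {text[i:]!r}", line)
            group = text[i + 1 : j]
            if not group or not all(c.isdigit() for c in group):
                raise MatrixParseError(f"bad polymorphic group {group!r}", line)
            cells.append(frozenset(int(c) for c in group))
            i = j + 1
        else:
            raise MatrixParseError(f"unknown state symbol {ch!r}", line)
    return cells


def _cell_to_string(cell) -> str:
    if cell is MISSING:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return "{" + "".join(str(s) for s in sorted(cell)) + "}"


def _row_to_string(row) -> str:
    return "".join(_cell_to_string(c) for c in row)


# ---------------------------------------------------------------------------
# dialect I/O

_DIALECTS = ("nexus", "tnt", "table")


def read_matrix(source, dialect: str) -> CharacterMatrix:
    """Read a character matrix from text or a text stream.

    ``dialect`` is one of ``"nexus"`` (#NEXUS with a CHARACTERS or DATA
    block), ``"tnt"`` (Hennig86/TNT ``xread``), or ``"table"``
    (tab/whitespace-delimited, first column the taxon label).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    if dialect == "nexus":
        return _read_nexus(text)
    if dialect == "tnt":
        return _read_tnt(text)
    if dialect == "table":
        return _read_table(text)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def write_matrix(matrix: CharacterMatrix, dialect: str) -> str:
    """Serialize ``matrix``; ``read_matrix(write_matrix(m), d) == m``."""
    for row in matrix._rows:
        for cell in row:
            if cell is not MISSING and max(cell) > 9:
                raise ValueError(
                    "state codes above 9 cannot be written as single symbols"
                )
    if dialect == "nexus":
        return _write_nexus(matrix)
    if dialect == "tnt":
        return _write_tnt(matrix)
    if dialect == "table":
        return _write_table(matrix)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


# -- NEXUS ------------------------------------------------------------------
# Reading goes through dendropy (the standard NEXUS implementation);
# writing emits a fixed minimal document so golden files are stable.


def _read_nexus(text: str) -> CharacterMatrix:
    import dendropy

    try:
        dm = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus"
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise MatrixParseError(f"NEXUS parse failure: {exc}") from None
    if len(dm) == 0:
        raise MatrixParseError("NEXUS document contains no character rows")
    taxa = [t.label for t in dm.taxon_namespace]
    rows = []
    for taxon in dm.taxon_namespace:
        seq = dm[taxon]
        cells = []
        for s in seq:
            symbol = s.symbol
            if symbol in ("?", "-"):
                cells.append(MISSING)
            elif symbol is not None and symbol.isdigit():
                cells.append(frozenset((int(symbol),)))
            else:
                members = frozenset(
                    int(m.symbol) for m in s.member_states
                )
                cells.append(members if members else MISSING)
        rows.append(cells)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise MatrixParseError("NEXUS rows have unequal lengths")
    return CharacterMatrix(taxa, rows)


def _quote_label(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _write_nexus(matrix: CharacterMatrix) -> str:
    symbols = sorted(
        {
            s
            for row in matrix._rows
            for cell in row
            if cell is not MISSING
            for s in cell
        }
    ) or [0]
    sym = '"' + "".join(str(s) for s in symbols) + '"'
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN TAXA;\n")
    out.write(f"    DIMENSIONS NTAX={matrix.n_taxa};\n    TAXLABELS\n")
    for t in matrix.taxa:
        out.write(f"        {_quote_label(t)}\n")
    out.write("    ;\nEND;\n\nBEGIN CHARACTERS;\n")
    out.write(f"    DIMENSIONS NCHAR={matrix.n_char};\n")
    out.write(f"    FORMAT DATATYPE=STANDARD SYMBOLS={sym} MISSING=? GAP=-;\n")
    out.write("    MATRIX\n")
    width = max(len(_quote_label(t)) for t in matrix.taxa) + 2
    for t, row in zip(matrix.taxa, matrix._rows):
        out.write(f"        {_quote_label(t):<{width}}{_row_to_string(row)}\n")
    out.write("    ;\nEND;\n")
    return out.getvalue()


# -- TNT / Hennig86 ---------------------------------------------------------
# xread 'title' nchar ntax, then label + state string per row, ";" to end.
# TNT labels are single tokens; spaces in labels round-trip as underscores.


def _read_tnt(text: str) -> CharacterMatrix:
    body = re.sub(r"'[^']*'", " ", text, count=1)  # drop optional title
    m = re.search(r"\bxread\b", body, flags=re.IGNORECASE)
    if not m:
        raise MatrixParseError("no xread command found")
    rest = body[m.end() :]
    end = rest.find(";")
    if end < 0:
        raise MatrixParseError("xread block not terminated by ';'")
    tokens = rest[:end].split()
    if len(tokens) < 2:
        raise MatrixParseError("xread header missing nchar/ntax")
    try:
        n_char, n_tax = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise MatrixParseError(
            f"bad xread dimensions {tokens[:2]!r}"
        ) from None
    taxa, rows = [], []
    pos = 2
    while pos < len(tokens):
        label = tokens[pos].replace("_", " ")
        pos += 1
        states = ""
        while pos < len(tokens) and _is_state_token(tokens[pos]):
            states += tokens[pos]
            pos += 1
        cells = _cells_from_string(states)
        if len(cells) != n_char:
            raise MatrixParseError(
                f"taxon {label!r}: {len(cells)} states, expected {n_char}"
            )
        taxa.append(label)
        rows.append(cells)
    if len(taxa) != n_tax:
        raise MatrixParseError(f"{len(taxa)} rows, header says {n_tax}")
    return CharacterMatrix(taxa, rows)


def _is_state_token(tok: str) -> bool:
    return bool(re.fullmatch(r"[0-9?\-{}\[\]()]+", tok))


def _write_tnt(matrix: CharacterMatrix) -> str:
    for t in matrix.taxa:
        if "_" in t:
            raise ValueError(
                f"taxon {t!r} contains '_', which the TNT dialect reserves "
                "for spaces"
            )
    out = io.StringIO()
    out.write("xread 'character matrix'\n")
    out.write(f"{matrix.n_char} {matrix.n_taxa}\n")
    width = max(len(t) for t in matrix.taxa) + 2
    for t, row in zip(matrix.taxa, matrix._rows):
        out.write(f"{t.replace(' ', '_'):<{width}}{_row_to_string(row)}\n")
    out.write(";\n")
    return out.getvalue()


# -- delimited table --------------------------------------------------------


def _read_table(text: str) -> CharacterMatrix:
    taxa, rows = [], []
    n_char = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            label, _, states = line.partition("\t")
            cells = _cells_from_string(states.replace("\t", ""), lineno)
        else:
            parts = line.split()
            label, cells = parts[0], _cells_from_string(
                "".join(parts[1:]), lineno
            )
        label = label.strip()
        if label in taxa:
            raise MatrixParseError(f"duplicate taxon {label!r}", lineno)
        if n_char is None:
            n_char = len(cells)
        elif len(cells) != n_char:
            raise MatrixParseError(
                f"taxon {label!r}: {len(cells)} states, expected {n_char}",
                lineno,
            )
        taxa.append(label)
        rows.append(cells)
    if not taxa:
        raise MatrixParseError("empty table")
    return CharacterMatrix(taxa, rows)


def _write_table(matrix: CharacterMatrix) -> str:
    lines = []
    for t, row in zip(matrix.taxa, matrix._rows):
        cells = "\t".join(_cell_to_string(c) for c in row)
        lines.append(f"{t}\t{cells}")
    return "\n".join(lines) + "\n"
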
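"""Morphological character matrices: containers, validation, NEXUS/TNT IO.

The matrix model follows standard practice for discrete morphological data:

* each cell is a *state set* — a singleton for an ordinary observation, a
  multi-element set for a polymorphic coding (``{01}``, ``(01)`` or ``[01]``),
  and the empty set for missing data (``?``); the gap symbol ``-`` is treated
  as missing, since morphological matrices in this literature do not
  distinguish inapplicable from unknown;
* each character is binary, ordered (additive: a change from state *i* to
  state *j* costs ``|i - j|``) or unordered (any change costs 1).

Ordering is read from NEXUS ``ASSUMPTIONS``/``TYPESET`` directives or TNT
``ccode`` lines and written back the same way, so ``read(write(m)) == m``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .trees import Tree


class CharType(str, Enum):
    BINARY = "binary"
    ORDERED = "ordered"
    UNORDERED = "unordered"


class MatrixValidationError(ValueError):
    pass


class MatrixParseError(ValueError):
    pass


@dataclass(frozen=True)
class CharacterDefinition:
    """One column: 0-based index, free-text label, ordering class, state count."""

    index: int
    char_type: CharType
    n_states: int
    label: str = ""

    def __post_init__(self):
        if self.char_type is CharType.BINARY and self.n_states != 2:
            raise MatrixValidationError(
                f"character {self.index}: binary characters have exactly 2 states"
            )
        if self.char_type is not CharType.BINARY and self.n_states < 3:
            raise MatrixValidationError(
                f"character {self.index}: multistate characters need >= 3 states"
            )

    @property
    def is_multistate(self) -> bool:
        return self.n_states > 2


@dataclass
class MatrixSummary:
    n_taxa: int
    n_chars: int
    n_binary: int
    n_ordered: int
    n_unordered: int
    missing_fraction: float
    n_polymorphic_cells: int
    n_ingroup: int
    n_outgroup: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CharacterMatrix:
    """Taxa x characters of state sets, with per-character ordering classes."""

    taxa: list[str]
    cells: list[list[frozenset[int]]]
    characters: list[CharacterDefinition]
    ingroup: list[bool] | None = None

    def __post_init__(self):
        self.validate()

    # -- basic views --------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.characters)

    def column(self, j: int) -> list[frozenset[int]]:
        if not 0 <= j < self.n_chars:
            raise IndexError(f"character index {j} out of range")
        return [row[j] for row in self.cells]

    def row(self, taxon: str) -> list[frozenset[int]]:
        return self.cells[self.taxa.index(taxon)]

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon names: {dupes}")
        if len(self.cells) != len(self.taxa):
            raise MatrixValidationError(
                f"{len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        nc = len(self.characters)
        for i, row in enumerate(self.cells):
            if len(row) != nc:
                raise MatrixValidationError(
                    f"taxon {self.taxa[i]!r}: row length {len(row)} != {nc} characters"
                )
            for j, cell in enumerate(row):
                bad = [s for s in cell if not 0 <= s < self.characters[j].n_states]
                if bad:
                    raise MatrixValidationError(
                        f"taxon {self.taxa[i]!r}, character {j + 1}: state(s) {bad} "
                        f"outside declared alphabet of {self.characters[j].n_states}"
                    )
        if self.ingroup is not None and len(self.ingroup) != len(self.taxa):
            raise MatrixValidationError("ingroup flags must match the taxon list")

    # -- summaries ----------------------------------------------------

    def summarize(self) -> MatrixSummary:
        counts = {t: 0 for t in CharType}
        for c in self.characters:
            counts[c.char_type] += 1
        cells = [c for row in self.cells for c in row]
        missing = sum(1 for c in cells if not c)
        poly = sum(1 for c in cells if len(c) > 1)
        n_in = sum(self.ingroup) if self.ingroup is not None else self.n_taxa
        return MatrixSummary(
            n_taxa=self.n_taxa,
            n_chars=self.n_chars,
            n_binary=counts[CharType.BINARY],
            n_ordered=counts[CharType.ORDERED],
            n_unordered=counts[CharType.UNORDERED],
            missing_fraction=missing / max(1, len(cells)),
            n_polymorphic_cells=poly,
            n_ingroup=n_in,
            n_outgroup=self.n_taxa - n_in,
        )

    # -- derived matrices ---------------------------------------------

    def take_columns(self, indices: list[int]) -> "CharacterMatrix":
        chars = [
            CharacterDefinition(
                index=k,
                char_type=self.characters[j].char_type,
                n_states=self.characters[j].n_states,
                label=self.characters[j].label,
            )
            for k, j in enumerate(indices)
        ]
        cells = [[row[j] for j in indices] for row in self.cells]
        return CharacterMatrix(
            list(self.taxa), cells, chars,
            list(self.ingroup) if self.ingroup is not None else None,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.cells == other.cells
            and [c.char_type for c in self.characters]
            == [c.char_type for c in other.characters]
        )


# ---------------------------------------------------------------------------
# building a matrix from raw rows


def build_matrix(
    taxa: list[str],
    cells: list[list[frozenset[int]]],
    ordered: set[int],
    unordered: set[int] | None = None,
    ingroup: list[bool] | None = None,
    labels: list[str] | None = None,
) -> CharacterMatrix:
    """Assemble a matrix, inferring each character's state count from the data.

    ``ordered`` / ``unordered`` hold 0-based indices declared additive /
    non-additive.  A declared multistate character keeps its class even when
    only two states happen to be observed (the declaration is about the
    character's conception, not the sample); undeclared characters are binary
    when two states are realised and unordered otherwise.
    """
    unordered = unordered or set()
    n_chars = len(cells[0]) if cells else 0
    chars = []
    for j in range(n_chars):
        observed = set().union(*(row[j] for row in cells)) or {0}
        n_states = max(2, max(observed) + 1)
        if j in ordered:
            ctype = CharType.ORDERED
            n_states = max(3, n_states)
        elif j in unordered:
            ctype = CharType.UNORDERED
            n_states = max(3, n_states)
        elif n_states == 2:
            ctype = CharType.BINARY
        else:
            ctype = CharType.UNORDERED
        chars.append(
            CharacterDefinition(
                index=j,
                char_type=ctype,
                n_states=n_states,
                label=labels[j] if labels else "",
            )
        )
    return CharacterMatrix(taxa, cells, chars, ingroup)


# ---------------------------------------------------------------------------
# symbol-level parsing


_STATE_SYMBOLS = "0123456789"


def _parse_row(text: str, open_close: dict[str, str], where: str) -> list[frozenset[int]]:
    out: list[frozenset[int]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in " \t":
            i += 1
            continue
        if ch in "?-":
            out.append(frozenset())
            i += 1
        elif ch in _STATE_SYMBOLS:
            out.append(frozenset([int(ch)]))
            i += 1
        elif ch in open_close:
            close = open_close[ch]
            j = text.find(close, i + 1)
            if j < 0:
                raise MatrixParseError(f"{where}: unterminated state set {text[i:]!r}")
            states = frozenset(int(c) for c in text[i + 1 : j] if c in _STATE_SYMBOLS)
            if not states:
                raise MatrixParseError(f"{where}: empty state set {text[i:j+1]!r}")
            out.append(states)
            i = j + 1
        else:
            raise MatrixParseError(f"{where}: unexpected symbol {ch!r}")
    return out


def _format_cell(cell: frozenset[int], braces: str = "{}") -> str:
    if not cell:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return braces[0] + "".join(str(s) for s in sorted(cell)) + braces[1]


def _expand_ranges(tokens: list[str], sep: str, where: str) -> set[int]:
    """1-based (NEXUS, sep='-') or 0-based (TNT, sep='.') index lists."""
    out: set[int] = set()
    for tok in tokens:
        if sep in tok:
            a, b = tok.split(sep, 1)
            out.update(range(int(a), int(b) + 1))
        else:
            out.add(int(tok))
    if not out:
        raise MatrixParseError(f"{where}: empty character list")
    return out


# ---------------------------------------------------------------------------
# NEXUS


def parse_nexus_matrix(text: str) -> CharacterMatrix:
    lines = text.splitlines()
    if not lines or not lines[0].strip().upper().startswith("#NEXUS"):
        raise MatrixParseError("line 1: missing #NEXUS header")

    ntax = nchar = None
    taxa: list[str] = []
    rows: list[list[frozenset[int]]] = []
    ordered: set[int] = set()
    unordered: set[int] = set()
    outgroup_spec: str | None = None
    in_block = None
    in_matrix = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("BEGIN"):
            in_block = upper.split()[1].rstrip(";")
            continue
        if upper.startswith("END"):
            in_block, in_matrix = None, False
            continue
        if in_block in ("DATA", "CHARACTERS"):
            if upper.startswith("DIMENSIONS"):
                m = re.search(r"NTAX\s*=\s*(\d+)", upper)
                ntax = int(m.group(1)) if m else None
                m = re.search(r"NCHAR\s*=\s*(\d+)", upper)
                nchar = int(m.group(1)) if m else None
            elif upper.startswith("FORMAT"):
                pass  # symbols fixed to 0-9, missing ?, gap -
            elif upper.startswith("MATRIX"):
                in_matrix = True
            elif in_matrix:
                body = line.rstrip(";").strip()
                if body:
                    name, _, states = body.partition(" ")
                    if not states:
                        raise MatrixParseError(
                            f"line {lineno}: matrix row needs a name and states"
                        )
                    taxa.append(name.strip("'"))
                    rows.append(
                        _parse_row(states, {"{": "}", "(": ")"}, f"line {lineno}")
                    )
                if line.endswith(";"):
                    in_matrix = False
        elif in_block == "ASSUMPTIONS" and upper.startswith("TYPESET"):
            _, _, spec = line.partition("=")
            for part in spec.rstrip(";").split(","):
                kind, _, idxs = part.partition(":")
                one_based = _expand_ranges(idxs.split(), "-", f"line {lineno}")
                if kind.strip().lower() in ("ord", "ordered"):
                    ordered |= {i - 1 for i in one_based}
                elif kind.strip().lower() in ("unord", "unordered"):
                    unordered |= {i - 1 for i in one_based}
        elif in_block == "SETS" and upper.startswith("TAXSET"):
            m = re.match(r"TAXSET\s+OUTGROUP\s*=\s*(.*);?", line, re.IGNORECASE)
            if m:
                outgroup_spec = m.group(1).rstrip(";")

    if not taxa:
        raise MatrixParseError("no matrix rows found in any DATA/CHARACTERS block")
    if ntax is not None and len(taxa) != ntax:
        raise MatrixParseError(f"DIMENSIONS declares NTAX={ntax}, found {len(taxa)} rows")
    for name, row in zip(taxa, rows):
        if nchar is not None and len(row) != nchar:
            raise MatrixParseError(
                f"taxon {name!r}: {len(row)} characters, DIMENSIONS declares {nchar}"
            )

    ingroup = None
    if outgroup_spec is not None:
        toks = outgroup_spec.split()
        if all(re.fullmatch(r"\d+(-\d+)?", t) for t in toks):
            out_idx = {i - 1 for i in _expand_ranges(toks, "-", "TAXSET")}
        else:
            out_idx = {taxa.index(t.strip("'")) for t in toks}
        ingroup = [i not in out_idx for i in range(len(taxa))]

    return build_matrix(taxa, rows, ordered, unordered, ingroup=ingroup)


def write_nexus_matrix(m: CharacterMatrix) -> str:
    name_w = max(len(t) for t in m.taxa) + 2
    max_state = max(c.n_states for c in m.characters)
    out = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};",
        f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(_STATE_SYMBOLS[:max_state])}\""
        " MISSING=? GAP=-;",
        "  MATRIX",
    ]
    for name, row in zip(m.taxa, m.cells):
        safe = name if " " not in name else f"'{name}'"
        out.append(f"    {safe:<{name_w}}" + "".join(_format_cell(c) for c in row))
    out.append("  ;")
    out.append("END;")
    ordered = [c.index + 1 for c in m.characters if c.char_type is CharType.ORDERED]
    unordered = [
        c.index + 1
        for c in m.characters
        if c.char_type is CharType.UNORDERED
    ]
    if ordered or unordered:
        parts = []
        if ordered:
            parts.append("ord: " + " ".join(map(str, ordered)))
        if unordered:
            parts.append("unord: " + " ".join(map(str, unordered)))
        out += ["BEGIN ASSUMPTIONS;", "  TYPESET * default = " + ", ".join(parts) + ";", "END;"]
    if m.ingroup is not None and not all(m.ingroup):
        outg = [str(i + 1) for i, flag in enumerate(m.ingroup) if not flag]
        out += ["BEGIN SETS;", "  TAXSET outgroup = " + " ".join(outg) + ";", "END;"]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# TNT


def parse_tnt_matrix(text: str) -> CharacterMatrix:
    lines = [ln.strip() for ln in text.splitlines()]
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lower().startswith("xread"))
    except StopIteration:
        raise MatrixParseError("line 1: no xread block found") from None
    i = start + 1
    # optional quoted title
    while i < len(lines) and (not lines[i] or lines[i].startswith("'")):
        i += 1
    try:
        nchar, ntax = (int(x) for x in lines[i].split())
    except (ValueError, IndexError):
        raise MatrixParseError(f"line {i + 1}: expected 'nchar ntax'") from None
    i += 1
    taxa, rows = [], []
    while i < len(lines):
        line = lines[i].rstrip(";").strip()
        if line:
            name, _, states = line.partition(" ")
            taxa.append(name.strip("'"))
            rows.append(_parse_row(states, {"[": "]"}, f"line {i + 1}"))
        if lines[i].endswith(";"):
            break
        i += 1
    if len(taxa) != ntax:
        raise MatrixParseError(f"xread declares {ntax} taxa, found {len(taxa)} rows")
    for name, row in zip(taxa, rows):
        if len(row) != nchar:
            raise MatrixParseError(
                f"taxon {name!r}: {len(row)} characters, xread declares {nchar}"
            )
    ordered: set[int] = set()
    unordered: set[int] = set()
    for lineno, ln in enumerate(lines, start=1):
        if ln.lower().startswith("ccode"):
            mode = None
            for tok in ln[5:].rstrip(";").split():
                if tok in "+-":
                    mode = tok
                elif mode == "+":
                    idxs = _expand_ranges([tok], ".", f"line {lineno}")
                    ordered |= idxs
                    unordered -= idxs
                elif mode == "-":
                    idxs = _expand_ranges([tok], ".", f"line {lineno}")
                    unordered |= idxs
                    ordered -= idxs
    return build_matrix(taxa, rows, ordered, unordered)


def write_tnt_matrix(m: CharacterMatrix, title: str = "cladistron export") -> str:
    name_w = max(len(t) for t in m.taxa) + 2
    out = ["xread", f"'{title}'", f"{m.n_chars} {m.n_taxa}"]
    for name, row in zip(m.taxa, m.cells):
        safe = name.replace(" ", "_")
        out.append(f"{safe:<{name_w}}" + "".join(_format_cell(c, "[]") for c in row))
    out.append(";")
    ordered = [c.index for c in m.characters if c.char_type is CharType.ORDERED]
    unordered = [c.index for c in m.characters if c.char_type is CharType.UNORDERED]
    if ordered or unordered:
        parts = ["ccode"]
        if ordered:
            parts.append("+ " + " ".join(map(str, ordered)))
        if unordered:
            parts.append("- " + " ".join(map(str, unordered)))
        out.append(" ".join(parts) + ";")
    out.append("proc /;")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# file-level API


def read_matrix(path: str | Path, dialect: str = "nexus") -> CharacterMatrix:
    text = Path(path).read_text()
    if dialect == "nexus":
        return parse_nexus_matrix(text)
    if dialect == "tnt":
        return parse_tnt_matrix(text)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'nexus' or 'tnt')")


def write_matrix(m: CharacterMatrix, path: str | Path, dialect: str = "nexus") -> None:
    if dialect == "nexus":
        Path(path).write_text(write_nexus_matrix(m))
    elif dialect == "tnt":
        Path(path).write_text(write_tnt_matrix(m))
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'nexus' or 'tnt')")


def read_trees(path: str | Path, dialect: str = "newick") -> list[Tree]:
    text = Path(path).read_text()
    if text.lstrip().upper().startswith("#NEXUS"):
        dialect = "nexus"
    if dialect == "newick":
        return [
            Tree.from_newick(chunk.strip() + ";")
            for chunk in text.split(";")
            if chunk.strip()
        ]
    if dialect == "nexus":
        import dendropy

        tl = dendropy.TreeList.get(data=text, schema="nexus")
        return [
            Tree.from_newick(
                t.as_string(schema="newick", suppress_rooting=True).strip()
            )
            for t in tl
        ]
    raise ValueError(f"unknown dialect {dialect!r} (expected 'newick' or 'nexus')")


def write_trees(
    trees: list[Tree], path: str | Path, dialect: str = "newick", lengths: bool = False
) -> None:
    if dialect == "newick":
        Path(path).write_text(
            "\n".join(t.to_newick(lengths=lengths) for t in trees) + "\n"
        )
    elif dialect == "nexus":
        out = ["#NEXUS", "BEGIN TREES;"]
        for i, t in enumerate(trees, start=1):
            out.append(f"  TREE tree_{i} = {t.to_newick(lengths=lengths)}")
        out += ["END;"]
        Path(path).write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'newick' or 'nexus')")
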
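"""PHI-style degenerate protein motifs: parsing, derivation, scanning.

A pattern such as ``KX[KR]XXR[ED]XWL[ML]`` is an ordered list of
positions, each either a *literal* residue, a *class* (a bracketed set
of allowed residues), or a *wildcard* (``X``, matching any residue).
Patterns of this form seed pattern-hit-initiated homology searches and
summarize near-invariant alignment columns embedded in otherwise
divergent protein families.

Scanning semantics: a window is reported when at least ``min_literal``
of the literal positions and ``min_class`` of the class positions match;
wildcard positions match any amino-acid letter but never a gap, and an
``X`` (unknown residue) in the *sequence* satisfies only wildcard
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .formats import AMINO_ACIDS, GAP, Alignment

#: Clustal-style "strong" conservation groups, used to decide whether an
#: alignment column represents a conservative substitution.
STRONG_GROUPS: tuple[frozenset, ...] = tuple(
    frozenset(g)
    for g in (
        "STA",
        "NEQK",
        "NHQK",
        "NDEQ",
        "QHRK",
        "MILV",
        "MILF",
        "HY",
        "FYW",
    )
)


class PatternError(ValueError):
    """Raised on a malformed PHI pattern string."""


@dataclass(frozen=True)
class Literal:
    residue: str

    def matches(self, ch: str) -> bool:
        return ch == self.residue

    def __str__(self) -> str:
        return self.residue


@dataclass(frozen=True)
class Class:
    residues: frozenset

    def matches(self, ch: str) -> bool:
        return ch in self.residues

    def __str__(self) -> str:
        # deterministic rendering; preserves declared order when built by
        # the parser (see MotifPattern.text round-trip note)
        return "[" + "".join(sorted(self.residues)) + "]"


@dataclass(frozen=True)
class Wildcard:
    def matches(self, ch: str) -> bool:
        return ch in AMINO_ACIDS or ch == "X"

    def __str__(self) -> str:
        return "X"


Position = Literal | Class | Wildcard


@dataclass(frozen=True)
class MotifPattern:
    """An ordered degenerate pattern over amino-acid positions."""

    positions: tuple[Position, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError("pattern must have at least one position")
        for p in self.positions:
            if isinstance(p, Literal) and p.residue not in AMINO_ACIDS:
                raise PatternError(f"literal {p.residue!r} is not an amino acid")
            if isinstance(p, Class):
                if len(p.residues) < 2:
                    raise PatternError("class positions need at least 2 residues")
                bad = set(p.residues) - AMINO_ACIDS
                if bad:
                    raise PatternError(
                        f"class contains non-amino-acid letter(s) {sorted(bad)}"
                    )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def text(self) -> str:
        return "".join(str(p) for p in self.positions)

    @property
    def n_literal(self) -> int:
        return sum(isinstance(p, Literal) for p in self.positions)

    @property
    def n_class(self) -> int:
        return sum(isinstance(p, Class) for p in self.positions)

    @property
    def n_wildcard(self) -> int:
        return sum(isinstance(p, Wildcard) for p in self.positions)


@dataclass(frozen=True)
class MotifHit:
    """One scan window meeting the match thresholds."""

    sequence_id: str
    offset: int
    matched_window: str
    n_literal_matched: int
    n_class_matched: int
    exact: bool


@dataclass(frozen=True)
class ColumnClassification:
    """Per-column verdicts for an alignment window.

    ``columns`` holds one entry per window column:
    ``("invariant", residue)``, ``("conservative", group_string)`` or
    ``("wildcard", None)``.
    """

    columns: tuple[tuple, ...]
    groups: tuple[frozenset, ...]

    @property
    def n_invariant(self) -> int:
        return sum(kind == "invariant" for kind, _ in self.columns)

    @property
    def n_conservative(self) -> int:
        return sum(kind == "conservative" for kind, _ in self.columns)


def parse_phi_pattern(text: str, name: str = "") -> MotifPattern:
    """Parse a PHI pattern string like ``KX[KR]XXR[ED]XWL[ML]``.

    One position per literal residue, per ``X``, and per bracket group.
    Errors report the 0-based character offset.
    """
    positions: list[Position] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "X":
            positions.append(Wildcard())
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(Literal(ch))
            i += 1
        elif ch == "[":
            close = text.find("]", i)
            if close == -1:
                raise PatternError(f"offset {i}: unclosed '['")
            inner = text[i + 1 : close]
            if not inner:
                raise PatternError(f"offset {i}: empty class '[]'")
            bad = set(inner) - AMINO_ACIDS
            if bad:
                raise PatternError(
                    f"offset {i}: illegal character(s) {sorted(bad)} in class"
                )
            if len(set(inner)) < 2:
                raise PatternError(f"offset {i}: class needs >= 2 distinct residues")
            positions.append(Class(frozenset(inner)))
            i = close + 1
        elif ch == "]":
            raise PatternError(f"offset {i}: unmatched ']'")
        else:
            raise PatternError(f"offset {i}: illegal character {ch!r}")
    if not positions:
        raise PatternError("empty pattern")
    return MotifPattern(tuple(positions), name=name)


def pattern_summary(pattern: MotifPattern) -> dict:
    """Counts of position kinds; components always sum to the length."""
    return {
        "length": len(pattern),
        "n_literal": pattern.n_literal,
        "n_class": pattern.n_class,
        "n_wildcard": pattern.n_wildcard,
    }


def scan_sequence(
    pattern: MotifPattern,
    sequence,
    min_literal: int | None = None,
    min_class: int | None = None,
) -> list[MotifHit]:
    """Scan one sequence for windows meeting the match thresholds.

    *sequence* is a :class:`~paralogon.formats.ProteinSequence` or a
    ``(id, residues)`` pair.  Thresholds default to requiring every
    literal and class position (exact matching).  Hits are returned in
    ascending offset order; a sequence shorter than the pattern yields
    an empty list.
    """
    if hasattr(sequence, "residues"):
        seq_id, residues = sequence.id, sequence.residues
    else:
        seq_id, residues = sequence
    if min_literal is None:
        min_literal = pattern.n_literal
    if min_class is None:
        min_class = pattern.n_class
    if min_literal > pattern.n_literal or min_class > pattern.n_class:
        raise ValueError("thresholds exceed the pattern's literal/class counts")
    m = len(pattern)
    hits: list[MotifHit] = []
    for offset in range(len(residues) - m + 1):
        window = residues[offset : offset + m]
        n_lit = n_cls = 0
        ok = True
        for pos, ch in zip(pattern.positions, window):
            if isinstance(pos, Wildcard):
                # wildcard positions have no threshold slack: a gap (or
                # anything outside the alphabet) disqualifies the window
                if not pos.matches(ch):
                    ok = False
                    break
            elif ch != GAP and ch != "X" and pos.matches(ch):
                if isinstance(pos, Literal):
                    n_lit += 1
                else:
                    n_cls += 1
        if not ok:
            continue
        if n_lit >= min_literal and n_cls >= min_class:
            hits.append(
                MotifHit(
                    sequence_id=seq_id,
                    offset=offset,
                    matched_window=window,
                    n_literal_matched=n_lit,
                    n_class_matched=n_cls,
                    exact=(n_lit == pattern.n_literal and n_cls == pattern.n_class),
                )
            )
    return hits


def scan_sequences(
    pattern: MotifPattern,
    sequences: Sequence,
    min_literal: int | None = None,
    min_class: int | None = None,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for seq in sequences:
        hits.extend(scan_sequence(pattern, seq, min_literal, min_class))
    return hits


def derive_pattern(
    alignment: Alignment,
    window_start: int,
    window_end: int,
    groups: Sequence[frozenset] = STRONG_GROUPS,
) -> tuple[MotifPattern, ColumnClassification]:
    """Derive a degenerate pattern from an alignment window.

    Per column: *invariant* (exactly one residue, no gaps) becomes a
    literal; *conservative* (all residues inside one substitution group,
    no gaps) becomes a class recording the observed residue set; any
    other column — including any column containing a gap or an unknown
    residue — becomes a wildcard.  When the observed residues fit
    several groups, the first group in declared order is recorded.
    """
    if not (0 <= window_start < window_end <= alignment.n_columns):
        raise ValueError(
            f"window [{window_start}, {window_end}) outside alignment "
            f"with {alignment.n_columns} columns"
        )
    groups = tuple(frozenset(g) for g in groups)
    positions: list[Position] = []
    verdicts: list[tuple] = []
    for j in range(window_start, window_end):
        col = alignment.column(j)
        residues = set(col)
        if GAP in residues or "X" in residues:
            positions.append(Wildcard())
            verdicts.append(("wildcard", None))
            continue
        if len(residues) == 1:
            (r,) = residues
            positions.append(Literal(r))
            verdicts.append(("invariant", r))
            continue
        group = next((g for g in groups if residues <= g), None)
        if group is not None and len(residues) >= 2:
            positions.append(Class(frozenset(residues)))
            verdicts.append(("conservative", "".join(sorted(group))))
        else:
            positions.append(Wildcard())
            verdicts.append(("wildcard", None))
    return (
        MotifPattern(tuple(positions)),
        ColumnClassification(tuple(verdicts), groups),
    )
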
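"""Cysteine-motif pattern language: parsing, rendering and matching.

A motif is an ordered list of cysteine anchors (``C``) and bounded
wildcard gaps (``X``, ``X{n}``, ``X{m,n}``).  A gap position matches any
residue *except* cysteine, each position independently.  Because gaps can
never consume a cysteine, the anchors of any match align to consecutive
cysteines of the target; matches are therefore unique per start position.

The matcher compiles motifs to standard regular expressions with lazy
bounded quantifiers (``[^C]{m,n}?``).  An independent backtracking
enumerator, :func:`enumerate_matches`, exists for cross-checking and is
not used on the production path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Union

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Unknown-residue letter produced when translating ambiguous codons.  It
#: is accepted in match targets: it does not satisfy a cysteine anchor but
#: does satisfy a wildcard position (it is not known to be C).
AMBIGUITY = "X"

_VALID_TARGET = STANDARD_AA | {AMBIGUITY}

#: Family labels admitted in motif databases.
FAMILIES = (
    "cyclotides",
    "defensins",
    "hevein-like",
    "thionins",
    "lipid-transfer",
    "snakins",
    "unknown",
)

#: Sentinel for a cysteine anchor inside ``Motif.elements``.
CYS = "C"


class MotifSyntaxError(ValueError):
    """Raised on malformed motif notation; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class AlphabetError(ValueError):
    """Raised when a match target contains a non-amino-acid character."""

    def __init__(self, char: str, position: int):
        super().__init__(
            f"invalid character {char!r} at position {position}: "
            "expected one of the 20 amino acids or 'X'"
        )
        self.char = char
        self.position = position


@dataclass(frozen=True)
class GapSpec:
    """A bounded non-cysteine gap.

    ``bare`` records that the gap was written as a lone ``X`` (exactly one
    residue) so rendering can reproduce the source notation; it carries no
    matching semantics.
    """

    min_len: int
    max_len: int
    bare: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.min_len < 0 or self.max_len < 0:
            raise ValueError("gap bounds must be non-negative")
        if self.min_len > self.max_len:
            raise ValueError(
                f"gap lower bound {self.min_len} exceeds upper bound {self.max_len}"
            )
        if self.bare and (self.min_len, self.max_len) != (1, 1):
            raise ValueError("a bare 'X' gap is exactly one residue wide")


Element = Union[str, GapSpec]


@dataclass(frozen=True)
class Motif:
    """A parsed cysteine motif with identifier and family label."""

    motif_id: str
    family: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not self.elements:
            raise ValueError("motif has no elements")
        n_anchors = 0
        prev_gap = False
        for el in self.elements:
            if el == CYS:
                n_anchors += 1
                prev_gap = False
            elif isinstance(el, GapSpec):
                if prev_gap:
                    raise ValueError("adjacent gaps are ambiguous and rejected")
                prev_gap = True
            else:
                raise ValueError(f"invalid motif element {el!r}")
        if n_anchors == 0:
            raise ValueError("motif must contain at least one cysteine anchor")

    @property
    def n_anchors(self) -> int:
        return sum(1 for el in self.elements if el == CYS)

    @property
    def specificity_range(self) -> int:
        """max_span - min_span; smaller means more specific."""
        lo, hi = span_bounds(self)
        return hi - lo

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_motif(self)


@dataclass(frozen=True, order=True)
class MatchSpan:
    """Half-open ``[start, end)`` span of a motif match on a target."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def parse_motif(text: str, motif_id: str = "", family: str = "unknown") -> Motif:
    """Parse motif notation into a :class:`Motif`.

    Accepted tokens: ``C`` (anchor), ``X`` (gap of exactly one residue),
    ``X{n}`` (gap of exactly *n*), ``X{m,n}`` (gap of *m* to *n* residues).
    Syntax errors report the 0-based character offset.
    """
    if not text:
        raise MotifSyntaxError("empty motif", 0)
    elements: list[Element] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "C":
            elements.append(CYS)
            i += 1
        elif ch == "X":
            start = i
            i += 1
            if i < n and text[i] == "{":
                close = text.find("}", i)
                if close == -1:
                    raise MotifSyntaxError("unclosed brace", i)
                body = text[i + 1 : close]
                parts = body.split(",")
                if not all(p.isdigit() for p in parts) or len(parts) > 2 or not body:
                    raise MotifSyntaxError(f"malformed gap bounds {{{body}}}", i)
                if len(parts) == 1:
                    lo = hi = int(parts[0])
                else:
                    lo, hi = int(parts[0]), int(parts[1])
                if lo > hi:
                    raise MotifSyntaxError(
                        f"gap lower bound {lo} exceeds upper bound {hi}", i
                    )
                gap = GapSpec(lo, hi)
                i = close + 1
            else:
                gap = GapSpec(1, 1, bare=True)
            if elements and isinstance(elements[-1], GapSpec):
                raise MotifSyntaxError("adjacent gaps are ambiguous", start)
            elements.append(gap)
        else:
            raise MotifSyntaxError(f"unknown token {ch!r}", i)
    try:
        return Motif(motif_id=motif_id, family=family, elements=tuple(elements))
    except ValueError as exc:
        raise MotifSyntaxError(str(exc), 0) from exc


def render_motif(motif: Motif) -> str:
    """Render a motif back to notation.

    Fixed gaps render as ``X{n}`` except gaps parsed from a bare ``X``,
    which render as ``X``; ranged gaps render as ``X{m,n}``.  This
    round-trips exactly with :func:`parse_motif`.
    """
    parts: list[str] = []
    for el in motif.elements:
        if el == CYS:
            parts.append("C")
        elif el.bare:
            parts.append("X")
        elif el.min_len == el.max_len:
            parts.append(f"X{{{el.min_len}}}")
        else:
            parts.append(f"X{{{el.min_len},{el.max_len}}}")
    return "".join(parts)


def span_bounds(motif: Motif) -> tuple[int, int]:
    """Minimum and maximum length of a substring the motif can match."""
    lo = hi = 0
    for el in motif.elements:
        if el == CYS:
            lo += 1
            hi += 1
        else:
            lo += el.min_len
            hi += el.max_len
    return lo, hi


@lru_cache(maxsize=4096)
def _compiled(elements: tuple[Element, ...]) -> re.Pattern[str]:
    parts = []
    for el in elements:
        if el == CYS:
            parts.append("C")
        else:
            # lazy quantifier: shortest match per start; [^C] makes
            # backtracking complete under the no-cysteine gap semantics
            parts.append(f"[^C]{{{el.min_len},{el.max_len}}}?")
    return re.compile("".join(parts))


def _validate_target(sequence: str) -> str:
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in _VALID_TARGET:
            raise AlphabetError(ch, pos)
    return seq


def find_matches(motif: Motif, sequence: str) -> list[MatchSpan]:
    """All matches of *motif* on *sequence*, one (shortest) per start.

    Input is uppercased; characters outside the 20 amino acids plus ``X``
    raise :class:`AlphabetError`.
    """
    seq = _validate_target(sequence)
    lo, _ = span_bounds(motif)
    if lo > len(seq):
        return []
    pat = _compiled(motif.elements)
    out: list[MatchSpan] = []
    if motif.elements[0] == CYS:
        starts: Iterable[int] = (i for i, c in enumerate(seq) if c == "C")
    else:
        starts = range(len(seq) - lo + 1)
    for i in starts:
        m = pat.match(seq, i)
        if m is not None:
            out.append(MatchSpan(i, m.end()))
    return out


def matches_anywhere(motif: Motif, sequence: str) -> bool:
    """True iff the motif matches somewhere in *sequence* (short-circuits)."""
    seq = _validate_target(sequence)
    lo, _ = span_bounds(motif)
    if lo > len(seq):
        return False
    return _compiled(motif.elements).search(seq) is not None


def enumerate_matches(motif: Motif, sequence: str) -> list[MatchSpan]:
    """Exhaustive backtracking matcher, independent of the regex engine.

    Enumerates every (start, gap-length assignment) and returns all
    distinct spans, sorted.  Intended for testing/cross-validation only.
    """
    seq = _validate_target(sequence)
    spans: set[MatchSpan] = set()
    elements = motif.elements
    n = len(seq)

    def walk(ei: int, pos: int, start: int) -> None:
        if ei == len(elements):
            spans.add(MatchSpan(start, pos))
            return
        el = elements[ei]
        if el == CYS:
            if pos < n and seq[pos] == "C":
                walk(ei + 1, pos + 1, start)
        else:
            for k in range(el.min_len, el.max_len + 1):
                if pos + k > n:
                    break
                if any(seq[pos + j] == "C" for j in range(k)):
                    # gaps cannot cross a cysteine; longer k only worse
                    break
                walk(ei + 1, pos + k, start)

    for i in range(n):
        walk(0, i, i)
    return sorted(spans)
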
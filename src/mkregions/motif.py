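"""Degenerate protein-motif scanning and per-region percent identity.

Patterns use PROSITE-like syntax: elements separated by ``-``, where an
element is a single-letter residue literal, a bracketed residue class like
``[ST]``, or a wildcard run ``X(m,n)`` / ``X(m)`` / bare ``X``.  This is
the dialect used by pattern-constrained BLAST searches, e.g. the
S/TP-region pattern ``[ST]-P-X(5,8)-S-P-X-[LIM]-S-P-I`` used to recover
divergent homologs of a rapidly evolving meiotic Polo-kinase inhibitor.

The matcher is implemented directly (backtracking over the element list)
rather than by compiling to a regular expression, so tests can hold it
against an independent regex translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .errors import MotifSyntaxError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class Literal:
    residue: str


@dataclass(frozen=True)
class ResidueClass:
    residues: frozenset[str]


@dataclass(frozen=True)
class Wildcard:
    min_len: int
    max_len: int


Element = Union[Literal, ResidueClass, Wildcard]


@dataclass(frozen=True)
class MotifPattern:
    """Parsed degenerate pattern: an ordered tuple of elements."""

    elements: tuple[Element, ...]

    def __post_init__(self):
        if all(isinstance(e, Wildcard) for e in self.elements):
            raise MotifSyntaxError("pattern needs at least one non-wildcard element", 0)

    @property
    def min_span(self) -> int:
        return sum(e.min_len if isinstance(e, Wildcard) else 1 for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_len if isinstance(e, Wildcard) else 1 for e in self.elements)


@dataclass(frozen=True)
class MotifHit:
    """One match: 1-based inclusive residue coordinates plus the substring."""

    sequence_id: str
    start: int
    end: int
    matched: str


def parse_pattern(text: str) -> MotifPattern:
    """Parse PROSITE-like pattern text into a :class:`MotifPattern`.

    Grammar per ``-``-separated token: ``A`` (literal), ``[ACD]`` (class),
    ``X`` (any one residue), ``X(m)`` (exactly m residues), ``X(m,n)``
    (m to n residues).  Whitespace inside wildcard parentheses is
    tolerated.  Malformed tokens raise :class:`MotifSyntaxError` carrying
    the character position of the offending token.
    """
    elements: list[Element] = []
    pos = 0
    for token in text.split("-"):
        token_stripped = token.strip()
        if not token_stripped:
            raise MotifSyntaxError("empty pattern element", pos)
        elements.append(_parse_element(token_stripped, pos))
        pos += len(token) + 1
    return MotifPattern(tuple(elements))


def _parse_element(token: str, pos: int) -> Element:
    if token.startswith("["):
        if not token.endswith("]") or len(token) < 3:
            raise MotifSyntaxError(f"malformed residue class {token!r}", pos)
        residues = token[1:-1].replace(" ", "")
        if not residues:
            raise MotifSyntaxError("empty residue class", pos)
        bad = set(residues) - _AA_SET
        if bad:
            raise MotifSyntaxError(
                f"invalid residue(s) {sorted(bad)} in class {token!r}", pos
            )
        return ResidueClass(frozenset(residues))
    if token[0] == "X":
        rest = token[1:].replace(" ", "")
        if not rest:
            return Wildcard(1, 1)
        if not (rest.startswith("(") and rest.endswith(")")):
            raise MotifSyntaxError(f"malformed wildcard {token!r}", pos)
        body = rest[1:-1]
        parts = body.split(",")
        try:
            if len(parts) == 1:
                m = n = int(parts[0])
            elif len(parts) == 2:
                m, n = int(parts[0]), int(parts[1])
            else:
                raise ValueError
        except ValueError:
            raise MotifSyntaxError(f"malformed wildcard bounds {token!r}", pos) from None
        if m < 0 or m > n:
            raise MotifSyntaxError(
                f"wildcard bounds must satisfy 0 <= m <= n, got ({m}, {n})", pos
            )
        return Wildcard(m, n)
    if len(token) == 1 and token in _AA_SET:
        return Literal(token)
    raise MotifSyntaxError(f"unrecognized pattern element {token!r}", pos)


def _match_from(
    elements: Sequence[Element], seq: str, i: int, e: int
) -> Optional[int]:
    """Shortest match length of elements[e:] against seq[i:], or None.

    An ``X`` in the subject sequence (unknown residue) satisfies only
    wildcard elements, never literals or classes.
    """
    if e == len(elements):
        return 0
    elem = elements[e]
    if isinstance(elem, (Literal, ResidueClass)):
        if i >= len(seq):
            return None
        ch = seq[i]
        ok = (
            ch == elem.residue
            if isinstance(elem, Literal)
            else ch in elem.residues
        )
        if not ok:
            return None
        rest = _match_from(elements, seq, i + 1, e + 1)
        return None if rest is None else 1 + rest
    # wildcard: try spans shortest-first so the overall match is minimal
    for span in range(elem.min_len, elem.max_len + 1):
        if i + span > len(seq):
            break
        rest = _match_from(elements, seq, i + span, e + 1)
        if rest is not None:
            return span + rest
    return None


def scan_sequence(
    pattern: MotifPattern, sequence: str, sequence_id: str = "seq"
) -> list[MotifHit]:
    """All matches of ``pattern`` in ``sequence``, one hit per start offset.

    Every start position that can begin a match is reported (overlapping
    hits included); for variable-length wildcards the shortest matching
    span at that start is returned.  Matching is case-insensitive on the
    subject; ``X`` in the subject matches only wildcard elements.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for start in range(len(seq) - pattern.min_span + 1):
        span = _match_from(pattern.elements, seq, start, 0)
        if span is not None:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=start + 1,
                    end=start + span,
                    matched=seq[start : start + span],
                )
            )
    return hits


def region_percent_identity(
    aligned_seq_a: str,
    aligned_seq_b: str,
    partition,
) -> dict[str, float]:
    """Percent identity per region between two aligned protein sequences.

    ``partition`` is a :class:`~mkregions.alignment_io.RegionPartition`
    whose coordinates are interpreted as 1-based alignment columns.  A
    column counts toward the denominator when at least one sequence has a
    residue there (columns gapped in both sequences are excluded); it
    scores as identical only when both sequences carry the same residue.
    Regions with an empty denominator return ``nan``.
    """
    if len(aligned_seq_a) != len(aligned_seq_b):
        raise ValueError(
            f"aligned sequences differ in length: "
            f"{len(aligned_seq_a)} vs {len(aligned_seq_b)}"
        )
    a = aligned_seq_a.upper()
    b = aligned_seq_b.upper()
    out: dict[str, float] = {}
    for region in partition.regions:
        lo, hi = region.start_codon - 1, region.end_codon  # alignment columns
        denom = 0
        ident = 0
        for i in range(lo, min(hi, len(a))):
            ca, cb = a[i], b[i]
            if ca == "-" and cb == "-":
                continue
            denom += 1
            if ca == cb and ca != "-":
                ident += 1
        out[region.name] = 100.0 * ident / denom if denom else float("nan")
    return out
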
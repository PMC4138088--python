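"""PROSITE pattern parsing and sequence scanning.

Implements the standard PROSITE pattern grammar (``-``-separated elements,
``x`` wildcard, ``[..]`` classes, ``{..}`` negated classes, ``(n)``/``(n,m)``
repeats, ``<``/``>`` anchors, optional trailing ``.``) and a scanner that
reports, for every start position with a match, the leftmost-longest span.

The matcher is deliberately independent of the :mod:`re` module: tests check
it against a regex translation oracle.

Only pattern-type accessions (low-numbered PS entries) are scannable;
profile (PS5xxxx) and Pfam accessions must be supplied as precomputed
annotations and are rejected here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .catalog import DomainAccession, DomainKind

__all__ = [
    "STANDARD_RESIDUES",
    "ElementKind",
    "PatternElement",
    "PrositePattern",
    "MatchSpan",
    "PatternSyntaxError",
    "parse_pattern",
    "render_pattern",
    "scan_sequence",
    "annotate_proteome",
    "load_pattern_table",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ElementKind(str, enum.Enum):
    EXACT = "exact"
    ANY = "any"
    CLASS = "class"
    NEGATED_CLASS = "negated_class"


@dataclass(frozen=True)
class PatternElement:
    element_kind: ElementKind
    residues: frozenset[str] = frozenset()
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.min_repeat < 0 or self.max_repeat < self.min_repeat:
            raise ValueError(f"bad repeat range ({self.min_repeat},{self.max_repeat})")
        if self.element_kind is ElementKind.EXACT and len(self.residues) != 1:
            raise ValueError("exact element needs exactly one residue")
        if self.element_kind in (ElementKind.CLASS, ElementKind.NEGATED_CLASS):
            if not self.residues:
                raise ValueError("residue class must be non-empty")
        if self.element_kind is ElementKind.ANY and self.residues:
            raise ValueError("wildcard element carries no residues")

    def accepts(self, residue: str) -> bool:
        """One-residue acceptance.

        The wildcard accepts any residue letter, including ambiguity codes
        such as X; exact/class/negated-class elements accept only the 20
        standard letters, so X never satisfies a constrained position.
        """
        if self.element_kind is ElementKind.ANY:
            return "A" <= residue <= "Z"
        if residue not in STANDARD_RESIDUES:
            return False
        if self.element_kind is ElementKind.EXACT or self.element_kind is ElementKind.CLASS:
            return residue in self.residues
        return residue not in self.residues  # negated class


@dataclass(frozen=True)
class PrositePattern:
    accession: DomainAccession
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern needs at least one element")


@dataclass(frozen=True, order=True)
class MatchSpan:
    """1-based inclusive coordinates (ScanProsite convention)."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span [{self.start},{self.end}]")


class PatternSyntaxError(ValueError):
    """Pattern text rejected, naming the offending element index."""

    def __init__(self, element_index: int, message: str):
        self.element_index = element_index
        super().__init__(f"element {element_index}: {message}")


def _parse_repeat(token: str, idx: int) -> tuple[str, int, int]:
    """Split a trailing (n) / (n,m) repeat off one element token."""
    if not token.endswith(")"):
        return token, 1, 1
    open_paren = token.rfind("(")
    if open_paren < 0:
        raise PatternSyntaxError(idx, f"unbalanced parenthesis in {token!r}")
    body, spec = token[:open_paren], token[open_paren + 1 : -1]
    parts = spec.split(",")
    try:
        if len(parts) == 1:
            lo = hi = int(parts[0])
        elif len(parts) == 2:
            lo, hi = int(parts[0]), int(parts[1])
        else:
            raise ValueError
    except ValueError:
        raise PatternSyntaxError(idx, f"bad repeat spec ({spec})") from None
    if lo < 0 or hi < lo:
        raise PatternSyntaxError(idx, f"bad repeat range ({spec})")
    return body, lo, hi


def parse_pattern(text: str, accession: DomainAccession) -> PrositePattern:
    """Parse PROSITE pattern syntax into a :class:`PrositePattern`.

    Raises :class:`PatternSyntaxError` on grammar violations and
    :class:`ValueError` if ``accession`` is not pattern-kind.
    """
    if accession.kind is not DomainKind.PATTERN:
        raise ValueError(
            f"{accession}: only pattern-type PS accessions are scannable "
            f"(got kind {accession.kind.value})"
        )
    text = text.strip()
    if text.endswith("."):
        text = text[:-1]
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    if not text:
        raise PatternSyntaxError(0, "empty pattern")
    elements: list[PatternElement] = []
    for idx, token in enumerate(text.split("-")):
        token = token.strip()
        body, lo, hi = _parse_repeat(token, idx)
        if not body:
            raise PatternSyntaxError(idx, "empty element")
        if "<" in body or ">" in body:
            raise PatternSyntaxError(idx, "anchors allowed only at pattern ends")
        if body == "x":
            elements.append(PatternElement(ElementKind.ANY, frozenset(), lo, hi))
            continue
        if body.startswith("["):
            if not body.endswith("]"):
                raise PatternSyntaxError(idx, f"unbalanced bracket in {body!r}")
            kind, residues = ElementKind.CLASS, body[1:-1]
        elif body.startswith("{"):
            if not body.endswith("}"):
                raise PatternSyntaxError(idx, f"unbalanced brace in {body!r}")
            kind, residues = ElementKind.NEGATED_CLASS, body[1:-1]
        else:
            kind, residues = ElementKind.EXACT, body
        residues = residues.upper()
        if not residues:
            raise PatternSyntaxError(idx, "empty residue class")
        bad = set(residues) - STANDARD_RESIDUES
        if bad:
            raise PatternSyntaxError(idx, f"unknown residue letter(s) {sorted(bad)}")
        if kind is ElementKind.EXACT and len(residues) > 1:
            raise PatternSyntaxError(idx, f"bare element {body!r} must be one residue")
        elements.append(PatternElement(kind, frozenset(residues), lo, hi))
    return PrositePattern(accession, tuple(elements), anchored_start, anchored_end)


def render_pattern(pattern: PrositePattern) -> str:
    """Grammar-equivalent textual form (inverse of :func:`parse_pattern`)."""
    parts = []
    for el in pattern.elements:
        if el.element_kind is ElementKind.ANY:
            body = "x"
        elif el.element_kind is ElementKind.EXACT:
            body = next(iter(el.residues))
        elif el.element_kind is ElementKind.CLASS:
            body = "[" + "".join(sorted(el.residues)) + "]"
        else:
            body = "{" + "".join(sorted(el.residues)) + "}"
        if (el.min_repeat, el.max_repeat) != (1, 1):
            if el.min_repeat == el.max_repeat:
                body += f"({el.min_repeat})"
            else:
                body += f"({el.min_repeat},{el.max_repeat})"
        parts.append(body)
    text = "-".join(parts)
    if pattern.anchored_start:
        text = "<" + text
    if pattern.anchored_end:
        text += ">"
    return text + "."


def _match_ends(pattern: PrositePattern, seq: str, start: int) -> set[int]:
    """All end offsets (exclusive) of matches beginning at 0-based ``start``."""
    positions = {start}
    for el in pattern.elements:
        nxt: set[int] = set()
        for pos in positions:
            # consume min_repeat..max_repeat accepted residues
            p = pos
            ok = True
            for _ in range(el.min_repeat):
                if p >= len(seq) or not el.accepts(seq[p]):
                    ok = False
                    break
                p += 1
            if not ok:
                continue
            nxt.add(p)
            for _ in range(el.max_repeat - el.min_repeat):
                if p >= len(seq) or not el.accepts(seq[p]):
                    break
                p += 1
                nxt.add(p)
        if not nxt:
            return set()
        positions = nxt
    return positions


def scan_sequence(
    pattern: PrositePattern, sequence: str, sequence_id: str
) -> list[MatchSpan]:
    """All matches of ``pattern`` in ``sequence``, one span per start position.

    Per start position the leftmost-longest expansion is reported; spans from
    different starts may overlap.  Case-insensitive; an empty sequence yields
    an empty list.
    """
    seq = sequence.upper()
    spans: list[MatchSpan] = []
    starts = [0] if pattern.anchored_start else range(len(seq))
    for start in starts:
        ends = _match_ends(pattern, seq, start)
        if pattern.anchored_end:
            ends = {e for e in ends if e == len(seq)}
        ends = {e for e in ends if e > start}  # zero-length matches are not spans
        if ends:
            spans.append(MatchSpan(sequence_id, start + 1, max(ends)))
    return spans


def annotate_proteome(
    patterns: Iterable[PrositePattern], fasta: str | Path
) -> dict[str, set[DomainAccession]]:
    """Assign pattern accessions to FASTA records with >= 1 match.

    Sequences with no matching pattern are absent from the result (sparse
    map).  Duplicate FASTA ids are a hard error.
    """
    patterns = list(patterns)
    result: dict[str, set[DomainAccession]] = {}
    seen_ids: set[str] = set()
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in seen_ids:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        seen_ids.add(record.id)
        sequence = str(record.seq)
        for pattern in patterns:
            if scan_sequence(pattern, sequence, record.id):
                result.setdefault(record.id, set()).add(pattern.accession)
    return result


def load_pattern_table(path: str | Path) -> list[PrositePattern]:
    """Load a TSV of (accession, pattern_text) pairs."""
    import csv

    patterns = []
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            accession = DomainAccession(row["accession"].strip())
            patterns.append(parse_pattern(row["pattern_text"], accession))
    return patterns
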
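"""Traffic-light classification of candidates and subunit identities.

Green: a single-subunit candidate with a vesicle-transport-related annotated
role and at least some chloroplast-localization support.  Yellow: every
other candidate (multi-subunit, unrelated or unknown role, or unsupported).
Red: a subunit identity for which the screen found no candidate at all.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

from .catalog import SubunitIdentity
from .localization import SupportLevel, SupportVerdict
from .screen import ProteomeRecord, ScreenResult

__all__ = [
    "DEFAULT_VESICLE_KEYWORDS",
    "Color",
    "CategoryVerdict",
    "SummaryCounts",
    "classify_locus",
    "classify_identity",
    "summarize",
]

#: Role-text keywords taken to indicate a known vesicle-transport role.
DEFAULT_VESICLE_KEYWORDS = ("vesicle transport", "endocytosis")


class Color(str, enum.Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


@dataclass(frozen=True)
class CategoryVerdict:
    subject: str  # locus or rendered identity
    color: Color
    rationale: str


@dataclass(frozen=True)
class SummaryCounts:
    total_candidates: int
    single_subunit: int
    multi_subunit: int
    green: int
    per_identity: Mapping[str, int]

    def __post_init__(self) -> None:
        assert self.total_candidates == self.single_subunit + self.multi_subunit
        assert self.green <= self.single_subunit


def classify_locus(
    record: ProteomeRecord,
    multi: bool,
    verdict: SupportVerdict,
    vesicle_keywords: Iterable[str] = DEFAULT_VESICLE_KEYWORDS,
) -> CategoryVerdict:
    """Color one candidate locus.

    Green needs all three: a vesicle-role keyword in the annotated role
    (substring, case-insensitive), a single-subunit hit, and a support level
    other than unsupported.  Otherwise yellow, with the failing rule(s) as
    the rationale.
    """
    role = record.role_text.lower()
    has_role = any(k.lower() in role for k in vesicle_keywords)
    problems: list[str] = []
    if multi:
        problems.append("commonly occurring domain (multi-subunit)")
    if not record.role_text.strip():
        problems.append("unknown role")
    elif not has_role:
        problems.append("non-vesicle role")
    if verdict.level is SupportLevel.UNSUPPORTED:
        problems.append("no chloroplast support")
    if not problems:
        return CategoryVerdict(
            record.locus,
            Color.GREEN,
            f"vesicle-transport role; localization support: {verdict.level.value}",
        )
    return CategoryVerdict(record.locus, Color.YELLOW, "; ".join(problems))


def classify_identity(
    identity: SubunitIdentity,
    result: ScreenResult,
    locus_verdicts: Mapping[str, CategoryVerdict],
    catalog_identities: Iterable[SubunitIdentity] | None = None,
) -> CategoryVerdict:
    """Color one subunit identity: red when it has no candidates, else the
    best color among its candidates (green beats yellow).

    When ``catalog_identities`` is given, an identity outside it raises
    ``KeyError`` (red is reserved for screened-but-empty identities).
    """
    if catalog_identities is not None and identity not in set(catalog_identities):
        raise KeyError(f"identity {identity} is not in the signature catalog")
    loci = result.by_identity.get(identity, frozenset())
    if not loci:
        return CategoryVerdict(identity.render(), Color.RED, "no candidate proteins")
    colors = {locus_verdicts[locus].color for locus in loci}
    if Color.GREEN in colors:
        return CategoryVerdict(identity.render(), Color.GREEN, "has a green candidate")
    return CategoryVerdict(identity.render(), Color.YELLOW, "only yellow candidates")


def summarize(
    result: ScreenResult, locus_verdicts: Mapping[str, CategoryVerdict]
) -> SummaryCounts:
    """Aggregate counts over a screen result and its locus verdicts."""
    missing = result.hit_loci - set(locus_verdicts)
    if missing:
        raise ValueError(f"verdicts missing for loci: {sorted(missing)}")
    green = sum(
        1
        for locus in result.hit_loci
        if locus_verdicts[locus].color is Color.GREEN
    )
    per_identity = {
        identity.render(): len(loci)
        for identity, loci in sorted(
            result.by_identity.items(), key=lambda kv: kv[0].render()
        )
    }
    return SummaryCounts(
        total_candidates=len(result.hit_loci),
        single_subunit=len(result.single_subunit_loci),
        multi_subunit=len(result.multi_subunit_loci),
        green=green,
        per_identity=per_identity,
    )
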
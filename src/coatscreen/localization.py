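"""Chloroplast-localization support verdicts for candidate loci.

Two evidence dialects are supported: ``consensus`` records carry the three
consensus predictor scores (chloroplast / mitochondrion / secretory) plus
experimental flags from two databases; ``single_predictor`` records carry a
single boolean chloroplast call (the rice workflow).

The verdict lattice formalizes the corroboration logic: a prediction source
(consensus score >= threshold, or the single-predictor call) crossed with
experimental support (either database) yields
strong > {experimental_only, consensus_only} > unsupported.
Verdicts annotate candidates; they never filter the candidate list.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .screen import ScreenResult

__all__ = [
    "CONSENSUS_THRESHOLD",
    "Dialect",
    "SupportLevel",
    "LocalizationEvidence",
    "SupportVerdict",
    "load_evidence_table",
    "consensus_supported",
    "integrate_evidence",
    "join_evidence",
]

logger = logging.getLogger(__name__)

#: Consensus score at or above which a chloroplast prediction counts as reliable.
CONSENSUS_THRESHOLD = 10.0


class Dialect(str, enum.Enum):
    CONSENSUS = "consensus"
    SINGLE_PREDICTOR = "single_predictor"


class SupportLevel(str, enum.Enum):
    STRONG = "strong"
    EXPERIMENTAL_ONLY = "experimental_only"
    CONSENSUS_ONLY = "consensus_only"
    UNSUPPORTED = "unsupported"


_LEVEL_RANK = {
    SupportLevel.UNSUPPORTED: 0,
    SupportLevel.CONSENSUS_ONLY: 1,
    SupportLevel.EXPERIMENTAL_ONLY: 1,
    SupportLevel.STRONG: 2,
}


@dataclass(frozen=True)
class LocalizationEvidence:
    locus: str
    dialect: Dialect
    cp_score: float | None = None
    mt_score: float | None = None
    sec_score: float | None = None
    suba: bool = False
    suba_methods: frozenset[str] = frozenset()  # subset of {"MS/MS", "GFP"}
    c2010: bool = False
    targetp_cp: bool | None = None

    def __post_init__(self) -> None:
        if self.dialect is Dialect.CONSENSUS:
            if self.cp_score is None or self.mt_score is None or self.sec_score is None:
                raise ValueError(f"{self.locus}: consensus dialect needs all three scores")
            if min(self.cp_score, self.mt_score, self.sec_score) < 0:
                raise ValueError(f"{self.locus}: negative consensus score")
        else:
            if self.targetp_cp is None:
                raise ValueError(f"{self.locus}: single_predictor dialect needs targetp_cp")


@dataclass(frozen=True)
class SupportVerdict:
    locus: str
    level: SupportLevel
    reasons: tuple[str, ...]


def load_evidence_table(path: str | Path) -> list[LocalizationEvidence]:
    """Load a TSV of evidence records (one row per locus)."""
    records = []
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            dialect = Dialect(row["dialect"].strip())
            def _score(key: str) -> float | None:
                raw = (row.get(key) or "").strip()
                return float(raw) if raw else None

            methods = frozenset(
                m.strip()
                for m in (row.get("suba_method") or "").split(",")
                if m.strip()
            )
            targetp_raw = (row.get("targetp_cp") or "").strip().lower()
            records.append(
                LocalizationEvidence(
                    locus=row["locus"].strip(),
                    dialect=dialect,
                    cp_score=_score("cp_score"),
                    mt_score=_score("mt_score"),
                    sec_score=_score("sec_score"),
                    suba=(row.get("suba") or "").strip().lower() == "yes",
                    suba_methods=methods,
                    c2010=(row.get("c2010") or "").strip().lower() == "yes",
                    targetp_cp={"true": True, "false": False}.get(targetp_raw),
                )
            )
    return records


def consensus_supported(
    ev: LocalizationEvidence, threshold: float = CONSENSUS_THRESHOLD
) -> bool:
    """True iff the chloroplast consensus score meets the reliability
    threshold (inclusive)."""
    if ev.dialect is not Dialect.CONSENSUS:
        raise ValueError(f"{ev.locus}: consensus_supported needs a consensus record")
    return ev.cp_score >= threshold


def integrate_evidence(
    ev: LocalizationEvidence, threshold: float = CONSENSUS_THRESHOLD
) -> SupportVerdict:
    """Classify one evidence record into the four-level support lattice."""
    reasons: list[str] = []
    if ev.dialect is Dialect.CONSENSUS:
        predicted = consensus_supported(ev, threshold)
        if predicted:
            reasons.append(f"consensus chloroplast score {ev.cp_score:g} >= {threshold:g}")
    else:
        predicted = bool(ev.targetp_cp)
        if predicted:
            reasons.append("single-predictor chloroplast call")
    experimental = ev.suba or ev.c2010
    if ev.suba:
        methods = ",".join(sorted(ev.suba_methods)) or "unspecified"
        reasons.append(f"SUBA ({methods})")
    if ev.c2010:
        reasons.append("Chloroplast 2010")
    if predicted and experimental:
        level = SupportLevel.STRONG
    elif experimental:
        level = SupportLevel.EXPERIMENTAL_ONLY
    elif predicted:
        level = SupportLevel.CONSENSUS_ONLY
    else:
        level = SupportLevel.UNSUPPORTED
    return SupportVerdict(ev.locus, level, tuple(reasons))


def join_evidence(
    result: ScreenResult,
    evidence: Iterable[LocalizationEvidence],
    threshold: float = CONSENSUS_THRESHOLD,
) -> dict[str, SupportVerdict]:
    """Map every hit locus to its support verdict.

    Loci without an evidence record get an unsupported verdict with reason
    "no record"; records for non-hit loci are ignored with a log line;
    duplicate records for one locus are a hard error.
    """
    by_locus: dict[str, LocalizationEvidence] = {}
    for ev in evidence:
        if ev.locus in by_locus:
            raise ValueError(f"duplicate evidence record for locus {ev.locus}")
        by_locus[ev.locus] = ev
    verdicts: dict[str, SupportVerdict] = {}
    for locus in sorted(result.hit_loci):
        ev = by_locus.get(locus)
        if ev is None:
            verdicts[locus] = SupportVerdict(locus, SupportLevel.UNSUPPORTED, ("no record",))
        else:
            verdicts[locus] = integrate_evidence(ev, threshold)
    ignored = set(by_locus) - result.hit_loci
    if ignored:
        logger.info("ignored evidence for %d non-hit loci", len(ignored))
    return verdicts
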
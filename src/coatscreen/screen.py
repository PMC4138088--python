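"""Match an annotated proteome against the signature catalog.

A proteome protein hits a subunit identity when its domain set is a superset
of any of that identity's signatures.  Loci hitting two or more distinct
identities form the multi-subunit ("commonly occurring domain") partition.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .catalog import (
    DomainAccession,
    SignatureCatalog,
    SubunitIdentity,
    SubunitSignature,
    parse_accession,
)

__all__ = [
    "ProteomeRecord",
    "CandidateHit",
    "ScreenResult",
    "load_proteome_table",
    "screen_proteome",
    "count_candidates",
    "compare_signatures",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteomeRecord:
    locus: str
    name: str
    domains: frozenset[DomainAccession]
    role_text: str = ""


@dataclass(frozen=True)
class CandidateHit:
    locus: str
    identity: SubunitIdentity
    matched_signature: SubunitSignature


@dataclass
class ScreenResult:
    hits: list[CandidateHit]
    by_identity: dict[SubunitIdentity, frozenset[str]]
    multi_subunit_loci: frozenset[str]
    single_subunit_loci: frozenset[str]
    unknown_accession_count: int = 0

    @property
    def hit_loci(self) -> frozenset[str]:
        return self.multi_subunit_loci | self.single_subunit_loci


def load_proteome_table(path: str | Path) -> list[ProteomeRecord]:
    """Load a TSV of locus, name, domains (``;``-separated), role_text."""
    records: list[ProteomeRecord] = []
    seen: set[str] = set()
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            locus = row["locus"].strip()
            if locus in seen:
                raise ValueError(f"{path}:{lineno}: duplicate locus {locus}")
            seen.add(locus)
            raw = (row.get("domains") or "").strip()
            domains = frozenset(
                parse_accession(t) for t in raw.split(";") if t.strip()
            )
            records.append(
                ProteomeRecord(
                    locus=locus,
                    name=(row.get("name") or "").strip(),
                    domains=domains,
                    role_text=(row.get("role_text") or "").strip(),
                )
            )
    return records


def screen_proteome(
    proteome: Iterable[ProteomeRecord], catalog: SignatureCatalog
) -> ScreenResult:
    """Screen every proteome record against every catalog signature.

    Each (locus, identity) pair is reported once, witnessed by the smallest
    matching signature (ties broken by source id).  Accessions in the
    proteome that appear in no signature are counted and logged, not errors.
    """
    if not catalog.signatures:
        raise ValueError("signature catalog is empty")
    known = set(catalog.domain_index)
    unknown_count = 0
    hits: list[CandidateHit] = []
    by_identity: dict[SubunitIdentity, set[str]] = {}
    per_locus: dict[str, set[SubunitIdentity]] = {}
    for record in proteome:
        unknown = record.domains - known
        if unknown:
            unknown_count += len(unknown)
            logger.warning(
                "locus %s: %d domain(s) not in any signature: %s",
                record.locus,
                len(unknown),
                ", ".join(sorted(a.accession for a in unknown)),
            )
        witnesses: dict[SubunitIdentity, SubunitSignature] = {}
        for signature in catalog.signatures:
            if signature.required <= record.domains:
                cur = witnesses.get(signature.identity)
                if cur is None or (len(signature.required), signature.source) < (
                    len(cur.required),
                    cur.source,
                ):
                    witnesses[signature.identity] = signature
        for identity, signature in witnesses.items():
            hits.append(CandidateHit(record.locus, identity, signature))
            by_identity.setdefault(identity, set()).add(record.locus)
            per_locus.setdefault(record.locus, set()).add(identity)
    hits.sort(key=lambda h: (h.locus, h.identity.render()))
    multi = frozenset(l for l, ids in per_locus.items() if len(ids) >= 2)
    single = frozenset(per_locus) - multi
    return ScreenResult(
        hits=hits,
        by_identity={i: frozenset(s) for i, s in by_identity.items()},
        multi_subunit_loci=multi,
        single_subunit_loci=single,
        unknown_accession_count=unknown_count,
    )


def count_candidates(
    result: ScreenResult, identity: SubunitIdentity, exclude_multi: bool = False
) -> int:
    """Number of candidate loci for one identity, optionally dropping
    multi-subunit loci."""
    loci = result.by_identity.get(identity)
    if loci is None:
        logger.warning("identity %s has no candidates in this screen", identity)
        return 0
    if exclude_multi:
        loci = loci - result.multi_subunit_loci
    return len(loci)


def compare_signatures(
    candidate: ProteomeRecord, reference: frozenset[DomainAccession] | set[DomainAccession]
) -> tuple[frozenset[DomainAccession], frozenset[DomainAccession]]:
    """(missing, extra) domain sets of a candidate against a reference set."""
    reference = frozenset(reference)
    return reference - candidate.domains, candidate.domains - reference
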
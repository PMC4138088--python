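"""End-to-end pipeline driver and deterministic report writers.

All tables are sorted (locus, then identity rendering) and serialized with
fixed formatting, so two runs on identical inputs are byte-identical except
for the timestamp, which is isolated inside the provenance block.
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from .catalog import QueryProtein, SignatureCatalog, build_catalog
from .classify import (
    DEFAULT_VESICLE_KEYWORDS,
    CategoryVerdict,
    SummaryCounts,
    classify_identity,
    classify_locus,
    summarize,
)
from .localization import (
    CONSENSUS_THRESHOLD,
    LocalizationEvidence,
    SupportVerdict,
    join_evidence,
)
from .screen import ProteomeRecord, ScreenResult, screen_proteome

__all__ = ["RunReport", "run_pipeline", "write_report", "load_summary"]


@dataclass
class RunReport:
    catalog: SignatureCatalog
    result: ScreenResult
    support: Mapping[str, SupportVerdict]
    locus_verdicts: Mapping[str, CategoryVerdict]
    identity_verdicts: Mapping[str, CategoryVerdict]
    summary: SummaryCounts
    notes: tuple[str, ...] = ()


def run_pipeline(
    queries: Iterable[QueryProtein],
    proteome: Iterable[ProteomeRecord],
    evidence: Iterable[LocalizationEvidence],
    vesicle_keywords: Sequence[str] = DEFAULT_VESICLE_KEYWORDS,
    consensus_threshold: float = CONSENSUS_THRESHOLD,
    notes: Sequence[str] = (),
) -> RunReport:
    """catalog -> screen -> evidence join -> classification -> summary."""
    proteome = list(proteome)
    catalog = build_catalog(queries)
    result = screen_proteome(proteome, catalog)
    support = join_evidence(result, evidence, consensus_threshold)
    by_locus = {record.locus: record for record in proteome}
    locus_verdicts = {
        locus: classify_locus(
            by_locus[locus],
            locus in result.multi_subunit_loci,
            support[locus],
            vesicle_keywords,
        )
        for locus in sorted(result.hit_loci)
    }
    identity_verdicts = {
        identity.render(): classify_identity(
            identity, result, locus_verdicts, catalog.identities
        )
        for identity in sorted(catalog.identities, key=lambda i: i.render())
    }
    summary = summarize(result, locus_verdicts)
    return RunReport(
        catalog=catalog,
        result=result,
        support=support,
        locus_verdicts=locus_verdicts,
        identity_verdicts=identity_verdicts,
        summary=summary,
        notes=tuple(notes),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    report: RunReport,
    out_dir: str | Path,
    input_paths: Mapping[str, str | Path] | None = None,
    config_echo: Mapping[str, object] | None = None,
) -> None:
    """Write candidates.tsv, verdicts.tsv and summary.json under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with (out_dir / "candidates.tsv").open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["locus", "system", "complex", "subunit", "witness_signature", "multi_flag"]
        )
        for hit in report.result.hits:
            writer.writerow(
                [
                    hit.locus,
                    hit.identity.system.value,
                    hit.identity.complex,
                    hit.identity.subunit,
                    ";".join(sorted(a.accession for a in hit.matched_signature.required)),
                    "multi" if hit.locus in report.result.multi_subunit_loci else "single",
                ]
            )

    with (out_dir / "verdicts.tsv").open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject", "color", "rationale"])
        for locus in sorted(report.locus_verdicts):
            v = report.locus_verdicts[locus]
            writer.writerow([v.subject, v.color.value, v.rationale])
        for key in sorted(report.identity_verdicts):
            v = report.identity_verdicts[key]
            writer.writerow([v.subject, v.color.value, v.rationale])

    provenance: dict[str, object] = {
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "input_checksums": {
            key: _sha256(Path(path)) for key, path in (input_paths or {}).items()
        },
        "config": dict(config_echo or {}),
        "warnings": {
            "unknown_accessions": report.result.unknown_accession_count,
        },
    }
    payload = {
        "summary": {
            "total_candidates": report.summary.total_candidates,
            "single_subunit": report.summary.single_subunit,
            "multi_subunit": report.summary.multi_subunit,
            "green": report.summary.green,
            "per_identity": dict(report.summary.per_identity),
        },
        "support_levels": {
            locus: report.support[locus].level.value
            for locus in sorted(report.support)
        },
        "notes": list(report.notes),
        "provenance": provenance,
    }
    with (out_dir / "summary.json").open("w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def load_summary(out_dir: str | Path) -> SummaryCounts:
    """Reload a written summary.json into :class:`SummaryCounts`."""
    with (Path(out_dir) / "summary.json").open(encoding="utf-8") as handle:
        payload = json.load(handle)
    block = payload["summary"]
    return SummaryCounts(
        total_candidates=block["total_candidates"],
        single_subunit=block["single_subunit"],
        multi_subunit=block["multi_subunit"],
        green=block["green"],
        per_identity=block["per_identity"],
    )
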
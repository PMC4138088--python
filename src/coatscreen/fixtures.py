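"""Packaged screening fixtures.

Two in-package datasets are shipped as the same TSV dialects the CLI
consumes, so they double as format documentation:

* ``arabidopsis`` — the chloroplast-annotated candidate loci with their
  domain annotations, consensus localization scores and experimental flags,
  plus the query-subunit signatures used to find them.
* ``rice`` — the chloroplast-predicted candidate loci from the complementary
  rice analysis (single-predictor evidence dialect).

Note on the rice counts: the source abstract mentions 14 rice proteins while
the detailed rice results enumerate 15 distinct loci; the fixture follows
the detailed enumeration.  See :data:`RICE_COUNT_NOTE`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .catalog import QueryProtein, load_query_table
from .localization import LocalizationEvidence, load_evidence_table
from .screen import ProteomeRecord, load_proteome_table

__all__ = ["FIXTURE_NAMES", "RICE_COUNT_NOTE", "load_fixture", "fixture_paths"]

FIXTURE_NAMES = ("arabidopsis", "rice")

RICE_COUNT_NOTE = (
    "rice fixture: the summary abstract of the source analysis reports 14 "
    "proteins, its detailed enumeration lists 15 distinct loci; this fixture "
    "encodes the 15-locus enumeration"
)


def fixture_paths(name: str) -> dict[str, Path]:
    """Filesystem paths of the three TSV files of one fixture."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    root = resources.files(__package__) / "fixtures"
    return {
        part: Path(str(root / f"{name}_{part}.tsv"))
        for part in ("queries", "proteome", "evidence")
    }


def load_fixture(
    name: str,
) -> tuple[list[QueryProtein], list[ProteomeRecord], list[LocalizationEvidence]]:
    """Load (queries, proteome, evidence) for one packaged fixture."""
    paths = fixture_paths(name)
    return (
        load_query_table(paths["queries"]),
        load_proteome_table(paths["proteome"]),
        load_evidence_table(paths["evidence"]),
    )
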
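"""Query-protein tables and per-subunit domain signatures.

Each query protein (one known vesicle-coat subunit from one organism)
contributes exactly one signature: the full set of Prosite/Pfam accessions
annotated on it.  The catalog indexes signatures by domain so that domains
shared between subunits ("commonly occurring" domains) can be reported.
"""

from __future__ import annotations

import csv
import enum
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DomainKind",
    "DomainAccession",
    "Organism",
    "System",
    "SubunitIdentity",
    "QueryProtein",
    "SubunitSignature",
    "SignatureCatalog",
    "QueryTableError",
    "parse_accession",
    "canonical_subunit",
    "load_query_table",
    "build_catalog",
    "shared_domain_report",
]

_ACCESSION_RE = re.compile(r"^(PS\d{5}|PF\d{5})$")


class DomainKind(str, enum.Enum):
    PATTERN = "pattern"    # Prosite pattern (PS0xxxx and other low-numbered PS)
    PROFILE = "profile"    # Prosite profile (PS5xxxx)
    FAMILY = "family"      # Pfam entry (PFxxxxx)


class Organism(str, enum.Enum):
    ARABIDOPSIS = "arabidopsis"
    YEAST = "yeast"
    MOUSE = "mouse"
    HUMAN = "human"
    RICE = "rice"


class System(str, enum.Enum):
    CCV = "CCV"
    COPI = "COPI"
    GTPASE = "GTPase"


@dataclass(frozen=True, order=True)
class DomainAccession:
    """A Prosite (PS*) or Pfam (PF*) identifier.

    ``kind`` is derivable from the accession prefix and is checked against it.
    Equality and hashing use the accession only, so the same accession with
    different free-text labels collapses in sets.
    """

    accession: str
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not _ACCESSION_RE.match(self.accession):
            raise ValueError(f"malformed domain accession: {self.accession!r}")

    @property
    def kind(self) -> DomainKind:
        if self.accession.startswith("PF"):
            return DomainKind.FAMILY
        if self.accession.startswith("PS5"):
            return DomainKind.PROFILE
        return DomainKind.PATTERN

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.accession


def parse_accession(text: str, label: str = "") -> DomainAccession:
    """Validate and wrap one accession string."""
    return DomainAccession(text.strip(), label)


# ASCII aliases for Greek subunit letters.  Subunit names are normalized to
# NFC Unicode; "beta-prime" style spellings are accepted on input.
_GREEK = {
    "alpha": "α",
    "beta": "β",
    "gamma": "γ",
    "delta": "δ",
    "epsilon": "ε",
    "zeta": "ζ",
    "mu": "μ",
    "sigma": "σ",
}
_GREEK_ALIAS_RE = re.compile(
    r"^(alpha|beta|gamma|delta|epsilon|zeta|mu|sigma)(-prime|'|′)?(\d*)$",
    re.IGNORECASE,
)


def canonical_subunit(name: str) -> str:
    """Canonical NFC form of a subunit name; resolves ASCII Greek aliases.

    "beta-prime" -> "β′", "mu2" -> "μ2", "heavy chain" -> unchanged.
    """
    name = unicodedata.normalize("NFC", name.strip())
    m = _GREEK_ALIAS_RE.match(name)
    if m:
        letter = _GREEK[m.group(1).lower()]
        prime = "′" if m.group(2) else ""
        return letter + prime + m.group(3)
    # normalize an apostrophe after a Greek letter to the prime character
    return re.sub(r"([α-ω])'", "\\1′", name)


@dataclass(frozen=True, order=True)
class SubunitIdentity:
    """One (system, complex, subunit) triple, e.g. (CCV, AP2, μ2)."""

    system: System
    complex: str
    subunit: str

    def render(self) -> str:
        """Stable rendering used for report ordering."""
        return f"{self.system.value}/{self.complex}/{self.subunit}"

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class QueryProtein:
    protein_id: str
    organism: Organism
    identity: SubunitIdentity
    domains: frozenset[DomainAccession]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"query protein {self.protein_id}: empty domain set")


@dataclass(frozen=True)
class SubunitSignature:
    """The full domain set of one query protein, keyed by its subunit identity."""

    identity: SubunitIdentity
    required: frozenset[DomainAccession]
    source: str  # query protein id

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError(f"signature from {self.source}: empty required set")


@dataclass
class SignatureCatalog:
    signatures: list[SubunitSignature]
    domain_index: dict[DomainAccession, frozenset[SubunitIdentity]]

    @property
    def identities(self) -> frozenset[SubunitIdentity]:
        return frozenset(s.identity for s in self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)


class QueryTableError(ValueError):
    """Malformed row in a query table, with its location."""

    def __init__(self, path: str | Path, row: int, message: str):
        self.path = str(path)
        self.row = row
        super().__init__(f"{path}:{row}: {message}")


_QUERY_COLUMNS = ("protein_id", "organism", "system", "complex", "subunit", "domains")


def load_query_table(path: str | Path) -> list[QueryProtein]:
    """Load a UTF-8 TSV of query proteins.

    Columns: protein_id, organism, system, complex, subunit,
    domains (``;``-separated accessions).  Duplicate rows collapse;
    malformed accessions or empty domain lists reject the row with a
    located error.
    """
    path = Path(path)
    queries: list[QueryProtein] = []
    seen: set[QueryProtein] = set()
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in _QUERY_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise QueryTableError(path, 1, f"missing columns: {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            raw = (row.get("domains") or "").strip()
            tokens = [t.strip() for t in raw.split(";") if t.strip()]
            if not tokens:
                raise QueryTableError(path, lineno, "empty domain list")
            domains = set()
            for token in tokens:
                try:
                    domains.add(parse_accession(token))
                except ValueError as exc:
                    raise QueryTableError(path, lineno, str(exc)) from exc
            try:
                organism = Organism(row["organism"].strip().lower())
                system = System(row["system"].strip())
            except ValueError as exc:
                raise QueryTableError(path, lineno, str(exc)) from exc
            identity = SubunitIdentity(
                system=system,
                complex=row["complex"].strip(),
                subunit=canonical_subunit(row["subunit"]),
            )
            query = QueryProtein(
                protein_id=row["protein_id"].strip(),
                organism=organism,
                identity=identity,
                domains=frozenset(domains),
            )
            if query not in seen:
                seen.add(query)
                queries.append(query)
    return queries


def build_catalog(queries: Iterable[QueryProtein]) -> SignatureCatalog:
    """Derive one signature per query protein and the inverted domain index."""
    signatures: list[SubunitSignature] = []
    seen: set[tuple[SubunitIdentity, frozenset[DomainAccession]]] = set()
    index: dict[DomainAccession, set[SubunitIdentity]] = {}
    for query in queries:
        key = (query.identity, query.domains)
        if key in seen:
            continue
        seen.add(key)
        signatures.append(
            SubunitSignature(
                identity=query.identity,
                required=query.domains,
                source=query.protein_id,
            )
        )
        for accession in query.domains:
            index.setdefault(accession, set()).add(query.identity)
    return SignatureCatalog(
        signatures=signatures,
        domain_index={a: frozenset(ids) for a, ids in index.items()},
    )


def shared_domain_report(
    catalog: SignatureCatalog,
) -> Mapping[DomainAccession, frozenset[SubunitIdentity]]:
    """Accessions appearing in signatures of >= 2 distinct subunit identities."""
    return {
        accession: identities
        for accession, identities in catalog.domain_index.items()
        if len(identities) >= 2
    }
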
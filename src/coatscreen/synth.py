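"""Synthetic screening instances with known ground truth.

The generator plants candidate loci into a background of decoy-only loci:
planted-single loci carry exactly one signature's required set (plus decoys),
planted-multi loci carry a domain shared by two or more single-domain
signatures.  Decoy accessions live in a reserved PF9xxxx namespace that must
be disjoint from the catalog, so recovery by the screen is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import DomainAccession, SignatureCatalog, SubunitIdentity
from .localization import Dialect, LocalizationEvidence
from .screen import ProteomeRecord

__all__ = [
    "DECOY_PREFIX",
    "GeneratorConfig",
    "GroundTruth",
    "generate_screen_instance",
    "generate_pattern_instances",
    "PatternInstance",
]

#: Reserved accession namespace for decoy domains (PF90000..PF99999).
DECOY_PREFIX = "PF9"


@dataclass(frozen=True)
class GeneratorConfig:
    n_background: int = 0
    n_planted_single: int = 0
    n_planted_multi: int = 0
    domain_pool_size: int = 20
    decoy_domain_rate: float = 0.3
    evidence_strong_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_planted_single, self.n_planted_multi) < 0:
            raise ValueError("negative count in generator config")
        if self.domain_pool_size < 1:
            raise ValueError("domain_pool_size must be >= 1")
        for frac in (self.decoy_domain_rate, self.evidence_strong_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    planted: dict[str, frozenset[SubunitIdentity]]
    expected_single: frozenset[str]
    expected_multi: frozenset[str]


def _decoy_pool(size: int) -> list[DomainAccession]:
    return [DomainAccession(f"PF9{i:04d}", "decoy") for i in range(size)]


def _identities_for(domains: frozenset[DomainAccession], catalog: SignatureCatalog):
    return frozenset(
        s.identity for s in catalog.signatures if s.required <= domains
    )


def generate_screen_instance(
    config: GeneratorConfig, catalog: SignatureCatalog
) -> tuple[list[ProteomeRecord], list[LocalizationEvidence], GroundTruth]:
    """Generate (proteome, evidence, ground truth), reproducibly from the seed."""
    if not catalog.signatures:
        raise ValueError("signature catalog is empty")
    for accession in catalog.domain_index:
        if accession.accession.startswith(DECOY_PREFIX):
            raise ValueError(
                f"catalog uses reserved decoy accession {accession.accession}"
            )
    rng = np.random.default_rng(config.seed)
    pool = _decoy_pool(config.domain_pool_size)

    # signatures whose required set triggers exactly one identity
    single_sigs = [
        s
        for s in catalog.signatures
        if len(_identities_for(s.required, catalog)) == 1
    ]
    if config.n_planted_single > 0 and not single_sigs:
        raise ValueError("catalog has no signature resolving to a single identity")
    # domains carried as a sole catalog domain by >= 2 identities
    shared_domains = sorted(
        {
            a
            for a in catalog.domain_index
            if len(_identities_for(frozenset([a]), catalog)) >= 2
        }
    )
    if config.n_planted_multi > 0 and not shared_domains:
        raise ValueError("catalog has no domain shared by two single-domain signatures")

    def decoys() -> set[DomainAccession]:
        mask = rng.random(config.domain_pool_size) < config.decoy_domain_rate
        return {pool[i] for i in np.flatnonzero(mask)}

    proteome: list[ProteomeRecord] = []
    planted: dict[str, frozenset[SubunitIdentity]] = {}
    counter = 0

    def next_locus() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:06d}"

    for _ in range(config.n_planted_single):
        sig = single_sigs[int(rng.integers(len(single_sigs)))]
        locus = next_locus()
        domains = frozenset(sig.required | decoys())
        proteome.append(ProteomeRecord(locus, f"planted {sig.identity}", domains))
        planted[locus] = _identities_for(domains, catalog)
    for _ in range(config.n_planted_multi):
        shared = shared_domains[int(rng.integers(len(shared_domains)))]
        locus = next_locus()
        domains = frozenset({shared} | decoys())
        proteome.append(ProteomeRecord(locus, f"planted shared {shared}", domains))
        planted[locus] = _identities_for(domains, catalog)
    for _ in range(config.n_background):
        locus = next_locus()
        proteome.append(ProteomeRecord(locus, "background", frozenset(decoys())))

    evidence: list[LocalizationEvidence] = []
    for record in proteome:
        strong = bool(rng.random() < config.evidence_strong_fraction)
        evidence.append(
            LocalizationEvidence(
                locus=record.locus,
                dialect=Dialect.CONSENSUS,
                cp_score=float(np.round(rng.uniform(10.0, 25.0), 1)) if strong else 0.0,
                mt_score=0.0,
                sec_score=0.0,
                suba=strong,
                suba_methods=frozenset({"MS/MS"}) if strong else frozenset(),
                c2010=strong,
            )
        )

    truth = GroundTruth(
        planted=planted,
        expected_single=frozenset(l for l, ids in planted.items() if len(ids) == 1),
        expected_multi=frozenset(l for l, ids in planted.items() if len(ids) >= 2),
    )
    return proteome, evidence, truth


# ---------------------------------------------------------------------------
# random PROSITE pattern instances with windowed-oracle expectations

@dataclass(frozen=True)
class PatternInstance:
    pattern_text: str
    sequences: dict[str, str]
    expected_matches: dict[str, tuple[tuple[int, int], ...]]


_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _random_pattern_text(rng: np.random.Generator, max_elements: int = 8) -> str:
    n = int(rng.integers(1, max_elements + 1))
    parts = []
    for _ in range(n):
        kind = rng.choice(["exact", "any", "class", "negated"])
        if kind == "exact":
            body = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
        elif kind == "any":
            body = "x"
        else:
            k = int(rng.integers(1, 4))
            idx = rng.choice(len(_ALPHABET), size=k, replace=False)
            residues = "".join(_ALPHABET[i] for i in sorted(idx))
            body = f"[{residues}]" if kind == "class" else f"{{{residues}}}"
        if rng.random() < 0.35:
            lo = int(rng.integers(0, 3))
            hi = lo + int(rng.integers(0, 3))
            body += f"({lo})" if lo == hi else f"({lo},{hi})"
        parts.append(body)
    text = "-".join(parts)
    if rng.random() < 0.15:
        text = "<" + text
    if rng.random() < 0.15:
        text += ">"
    return text + "."


def translate_to_regex(text: str) -> str:
    """Translate PROSITE pattern text to a Python regex (oracle path).

    Intentionally written against the grammar text, not against the parsed
    element representation, so it stays independent of the scanner.
    """
    import re as _re

    text = text.strip().rstrip(".")
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    out = []
    for token in text.split("-"):
        m = _re.fullmatch(r"(x|\[[A-Z]+\]|\{[A-Z]+\}|[A-Z])(?:\((\d+)(?:,(\d+))?\))?", token)
        if m is None:
            raise ValueError(f"cannot translate token {token!r}")
        body, lo, hi = m.group(1), m.group(2), m.group(3)
        if body == "x":
            piece = "[A-ZX]"  # wildcard also matches the unknown residue X
        elif body.startswith("["):
            piece = body
        elif body.startswith("{"):
            allowed = "".join(c for c in _ALPHABET if c not in set(body[1:-1]))
            piece = f"[{allowed}]"
        else:
            piece = body
        if lo is not None:
            piece += f"{{{lo},{hi or lo}}}"
        out.append(piece)
    regex = "".join(out)
    # anchors are applied by the caller through start/end restriction
    return regex


def windowed_regex_matches(
    pattern_text: str, sequence: str
) -> tuple[tuple[int, int], ...]:
    """Leftmost-longest spans by brute-force window enumeration.

    For every (start, end) window the translated regex is applied with
    ``fullmatch``; per start the longest accepted window is kept.  1-based
    inclusive coordinates.
    """
    import re as _re

    stripped = pattern_text.strip().rstrip(".")
    anchored_start = stripped.startswith("<")
    anchored_end = stripped.endswith(">")
    regex = _re.compile(translate_to_regex(pattern_text))
    seq = sequence.upper()
    spans = []
    starts = [0] if anchored_start else range(len(seq))
    for start in starts:
        ends = [
            end
            for end in range(start + 1, len(seq) + 1)
            if regex.fullmatch(seq, start, end) and regex.fullmatch(seq, start, end).end() == end
        ]
        if anchored_end:
            ends = [e for e in ends if e == len(seq)]
        if ends:
            spans.append((start + 1, max(ends)))
    return tuple(spans)


def generate_pattern_instances(n: int, seed: int) -> list[PatternInstance]:
    """Random grammar-valid patterns with oracle-computed expected matches."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    instances = []
    for i in range(n):
        text = _random_pattern_text(rng)
        sequences = {}
        for j in range(int(rng.integers(1, 4))):
            length = int(rng.integers(0, 40))
            # small alphabet raises the match rate
            letters = rng.choice(list("ACDGX"), size=length)
            sequences[f"seq{i}_{j}"] = "".join(letters)
        expected = {
            sid: windowed_regex_matches(text, seq) for sid, seq in sequences.items()
        }
        instances.append(PatternInstance(text, sequences, expected))
    return instances
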
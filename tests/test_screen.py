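"""Proteome screening against the catalog, with a brute-force subset oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from coatscreen.catalog import (
    DomainAccession,
    Organism,
    QueryProtein,
    build_catalog,
)
from coatscreen.screen import (
    ProteomeRecord,
    compare_signatures,
    count_candidates,
    screen_proteome,
)

from conftest import ident


def _acc(*names):
    return frozenset(DomainAccession(n) for n in names)


def _query(pid, identity, accessions):
    return QueryProtein(pid, Organism.YEAST, identity, _acc(*accessions))


@pytest.fixture()
def small_catalog():
    return build_catalog(
        [
            _query("lc", ident("CCV", "triskelion", "light chain"), ["PF01086"]),
            _query("b1", ident("CCV", "AP1", "β1"), ["PF01602"]),
            _query("fg", ident("COPI", "F-COPI", "γ"), ["PF01602", "PF08752"]),
        ]
    )


class TestScreenProteome:
    def test_single_domain_hit(self, small_catalog):
        result = screen_proteome(
            [ProteomeRecord("At2g40060", "AtCLC1", _acc("PF01086"))], small_catalog
        )
        assert result.by_identity[ident("CCV", "triskelion", "light chain")] == {
            "At2g40060"
        }

    def test_superset_matches_multiple_identities(self, small_catalog):
        result = screen_proteome(
            [ProteomeRecord("At4g34450", "", _acc("PF01602", "PF08752"))],
            small_catalog,
        )
        assert set(result.by_identity) == {
            ident("CCV", "AP1", "β1"),
            ident("COPI", "F-COPI", "γ"),
        }
        assert result.multi_subunit_loci == {"At4g34450"}

    def test_empty_domains_no_hits(self, small_catalog):
        result = screen_proteome(
            [ProteomeRecord("At1g00001", "", frozenset())], small_catalog
        )
        assert result.hits == [] and result.hit_loci == frozenset()

    def test_unknown_accessions_warn_not_error(self, small_catalog, caplog):
        record = ProteomeRecord("x", "", _acc("PF01086", "PF09999"))
        with caplog.at_level("WARNING", logger="coatscreen.screen"):
            result = screen_proteome([record], small_catalog)
        assert result.unknown_accession_count == 1
        assert result.hit_loci == {"x"}

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            screen_proteome([], build_catalog([]))

    def test_witness_is_smallest_signature(self, small_catalog):
        result = screen_proteome(
            [ProteomeRecord("a", "", _acc("PF01602", "PF08752"))], small_catalog
        )
        witness = {h.identity: h.matched_signature for h in result.hits}
        assert witness[ident("CCV", "AP1", "β1")].required == _acc("PF01602")
        assert witness[ident("COPI", "F-COPI", "γ")].required == _acc(
            "PF01602", "PF08752"
        )

    def test_hits_sorted_by_locus_then_identity(self, small_catalog):
        records = [
            ProteomeRecord("b", "", _acc("PF01086")),
            ProteomeRecord("a", "", _acc("PF01602", "PF08752")),
        ]
        result = screen_proteome(records, small_catalog)
        keys = [(h.locus, h.identity.render()) for h in result.hits]
        assert keys == sorted(keys)


class TestCountCandidates:
    def test_beta_prime_excluding_multi(self, arabidopsis_report):
        assert (
            count_candidates(
                arabidopsis_report.result,
                ident("COPI", "B-COPI", "β′"),
                exclude_multi=True,
            )
            == 8
        )

    def test_fcopi_gamma_only_common_domain_carrier(self, arabidopsis_report):
        identity = ident("COPI", "F-COPI", "γ")
        assert count_candidates(arabidopsis_report.result, identity, True) == 0
        assert count_candidates(arabidopsis_report.result, identity, False) == 1

    def test_unknown_identity_is_zero(self, arabidopsis_report):
        assert (
            count_candidates(
                arabidopsis_report.result, ident("CCV", "AP9", "ω"), True
            )
            == 0
        )

    def test_empty_proteome(self, small_catalog):
        result = screen_proteome([], small_catalog)
        assert count_candidates(result, ident("CCV", "AP1", "β1")) == 0


class TestCompareSignatures:
    def test_zeta_divergence(self):
        candidate = ProteomeRecord(
            "At1g08520", "AtCHLD", _acc("PS50234", "PF13519", "PF01078")
        )
        missing, extra = compare_signatures(candidate, _acc("PF01217"))
        assert missing == _acc("PF01217")
        assert extra == _acc("PS50234", "PF13519", "PF01078")

    def test_identical_sets(self):
        candidate = ProteomeRecord("x", "", _acc("PF01086"))
        assert compare_signatures(candidate, _acc("PF01086")) == (
            frozenset(),
            frozenset(),
        )

    def test_empty_candidate(self):
        candidate = ProteomeRecord("x", "", frozenset())
        missing, extra = compare_signatures(candidate, _acc("PF01086", "PF01602"))
        assert missing == _acc("PF01086", "PF01602") and extra == frozenset()


# -- randomized oracle + property tests --------------------------------------

_domains = [DomainAccession(f"PF{i:05d}") for i in range(1, 15)]
_identities = [
    ident("CCV", "AP1", s) for s in ("β1", "γ", "μ1", "σ1")
] + [ident("COPI", "B-COPI", s) for s in ("α", "β′", "ε")]


@st.composite
def _screen_instance(draw):
    n_sigs = draw(st.integers(1, 6))
    queries = [
        QueryProtein(
            f"q{i}",
            Organism.YEAST,
            draw(st.sampled_from(_identities)),
            draw(st.frozensets(st.sampled_from(_domains), min_size=1, max_size=4)),
        )
        for i in range(n_sigs)
    ]
    n_loci = draw(st.integers(0, 50))
    proteome = [
        ProteomeRecord(
            f"L{i:03d}",
            "",
            draw(st.frozensets(st.sampled_from(_domains), max_size=8)),
        )
        for i in range(n_loci)
    ]
    return build_catalog(queries), proteome


@settings(max_examples=100, deadline=None)
@given(_screen_instance())
def test_hits_equal_brute_force_subset_oracle(instance):
    catalog, proteome = instance
    result = screen_proteome(proteome, catalog)
    for record in proteome:
        for identity in {s.identity for s in catalog.signatures}:
            expected = any(
                s.required <= record.domains
                for s in catalog.signatures
                if s.identity == identity
            )
            got = record.locus in result.by_identity.get(identity, frozenset())
            assert got == expected


@settings(max_examples=100, deadline=None)
@given(_screen_instance())
def test_partition_invariant(instance):
    catalog, proteome = instance
    result = screen_proteome(proteome, catalog)
    assert result.multi_subunit_loci | result.single_subunit_loci == result.hit_loci
    assert not (result.multi_subunit_loci & result.single_subunit_loci)
    per_locus = {}
    for hit in result.hits:
        per_locus.setdefault(hit.locus, set()).add(hit.identity)
    for locus, identities in per_locus.items():
        assert (locus in result.multi_subunit_loci) == (len(identities) >= 2)


@settings(max_examples=60, deadline=None)
@given(_screen_instance(), st.sampled_from(_domains))
def test_monotone_under_domain_addition(instance, extra_domain):
    catalog, proteome = instance
    before = screen_proteome(proteome, catalog)
    grown = [
        ProteomeRecord(r.locus, r.name, r.domains | {extra_domain}, r.role_text)
        for r in proteome
    ]
    after = screen_proteome(grown, catalog)
    for identity, loci in before.by_identity.items():
        assert loci <= after.by_identity.get(identity, frozenset())


@settings(max_examples=60, deadline=None)
@given(_screen_instance(), st.data())
def test_removing_signature_never_creates_hit(instance, data):
    catalog, proteome = instance
    index = data.draw(st.integers(0, len(catalog.signatures) - 1))
    kept = [s for i, s in enumerate(catalog.signatures) if i != index]
    if not kept:
        return
    before = screen_proteome(proteome, catalog)
    reduced = build_catalog(
        [
            QueryProtein(s.source, Organism.YEAST, s.identity, s.required)
            for s in kept
        ]
    )
    after = screen_proteome(proteome, reduced)
    for identity, loci in after.by_identity.items():
        assert loci <= before.by_identity.get(identity, frozenset())


def test_fixture_counts(arabidopsis_report):
    result = arabidopsis_report.result
    expected = {
        ident("CCV", "triskelion", "heavy chain"): 1,
        ident("CCV", "triskelion", "light chain"): 1,
        ident("CCV", "AP1", "γ"): 5,
        ident("CCV", "AP2", "β2"): 5,
        ident("COPI", "B-COPI", "β′"): 8,
        ident("COPI", "F-COPI", "ζ"): 2,
    }
    for identity, count in expected.items():
        assert count_candidates(result, identity, exclude_multi=True) == count
    assert len(result.multi_subunit_loci) == 7
    assert len(result.hit_loci) == 29
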
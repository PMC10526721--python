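"""Curation layer: ingest with quarantine, referential integrity, pathway
and region queries, sqlite round trip."""

import pytest

from connectomatrix import DistanceType, UnknownPathwayError, UnknownUnitError
from connectomatrix.evidence import ingest_curation_file
from connectomatrix.fixtures import packaged_sidecar_path

TEN_PATHWAYS = {
    "SLF", "ILF", "CB", "OFF", "EmC", "UF", "IC",
    "corticopontine", "corticostriatal", "amygdalofugal",
}

HEADER = "region_a,region_b,type,pathway,era,publication,page,table,figure,tracer,species,notes\n"


def ingest_text(tmp_path, registry, text, sidecar=True):
    path = tmp_path / "curation.csv"
    path.write_text(HEADER + text)
    return ingest_curation_file(
        path, registry,
        sidecar_path=packaged_sidecar_path() if sidecar else None,
    )


class TestPackagedFixtureIngest:
    def test_ten_named_pathway_systems(self, fixture_db):
        assert TEN_PATHWAYS <= set(fixture_db.pathways)

    def test_no_quarantined_rows(self, registry):
        from connectomatrix.fixtures import build_fixture_db

        _, report = build_fixture_db("pre_dti", registry)
        assert report.ok
        assert report.n_accepted == report.n_rows

    def test_referential_integrity(self, fixture_db):
        for record in fixture_db.evidence_records.values():
            assert record.publication_ref in fixture_db.publications
        for assertion in fixture_db.assertions:
            assert assertion.region_a in fixture_db.registry
            assert assertion.region_b in fixture_db.registry
            for eid in assertion.evidence:
                assert eid in fixture_db.evidence_records

    def test_ingest_deterministic(self, registry, fixture_db):
        from connectomatrix.fixtures import build_fixture_db

        again, _ = build_fixture_db("pre_dti", registry)
        assert again.assertions == fixture_db.assertions
        assert again.evidence_records == fixture_db.evidence_records


class TestQuarantine:
    def test_typology_violation_quarantined(self, registry, tmp_path):
        db, report = ingest_text(
            tmp_path, registry,
            "F1,F2,3,SLF,pre_dti,dejerine1901,,,,,human,bad row\n",
        )
        assert report.n_accepted == 0
        assert len(report.quarantined) == 1
        assert "typology violation" in report.quarantined[0][1]
        assert db.assertions == []

    @pytest.mark.parametrize(
        "row,fragment",
        [
            ("ZZZ,F2,3,SLF,pre_dti,dejerine1901,,,,,human,", "unknown unit"),
            ("F2,AG,9,SLF,pre_dti,dejerine1901,,,,,human,", "invalid distance type"),
            ("F2,AG,3,SLF,jurassic,dejerine1901,,,,,human,", "invalid era"),
            ("F2,AG,3,made-up fascicle,pre_dti,dejerine1901,,,,,human,", "unknown pathway"),
            ("F2,AG,3,SLF,pre_dti,nobody9999,,,,,human,", "unknown publication"),
        ],
    )
    def test_per_row_diagnostics(self, registry, tmp_path, row, fragment):
        _, report = ingest_text(tmp_path, registry, row + "\n")
        assert len(report.quarantined) == 1
        assert fragment in report.quarantined[0][1]

    def test_empty_file(self, registry, tmp_path):
        db, report = ingest_text(tmp_path, registry, "")
        assert report.n_rows == 0 and report.ok
        assert db.assertions == [] and db.evidence_records == {}


class TestPathwayQueries:
    def test_slf_interconnects_the_exemplar_regions(self, fixture_db):
        assert {"F2", "AG"} <= fixture_db.pathway_regions("SLF")

    def test_synonym_and_case_insensitive_lookup(self, fixture_db):
        canonical = fixture_db.pathway_regions("SLF")
        assert fixture_db.pathway_regions("superior longitudinal fascicle") == canonical
        assert fixture_db.pathway_regions("Superior Longitudinal Fascicle") == canonical

    def test_unknown_pathway_raises(self, fixture_db):
        with pytest.raises(UnknownPathwayError):
            fixture_db.pathway_regions("made-up fascicle")

    def test_region_set_equals_assertion_endpoint_union(self, fixture_db):
        for name, pathway in fixture_db.pathways.items():
            endpoints = set()
            for a in fixture_db.assertions:
                if a.pathway_ref == name:
                    endpoints.update((a.region_a, a.region_b))
            assert pathway.region_set == frozenset(endpoints)


class TestRegionAndTypeQueries:
    def test_ag_long_range_group_includes_f2(self, fixture_db):
        groups = fixture_db.query_by_region("AG")
        partners = {
            (a.region_b if a.region_a == "AG" else a.region_a)
            for a in groups[DistanceType.LONG_RANGE]
        }
        assert "F2" in partners

    def test_grouping_matches_brute_force_scan(self, fixture_db):
        for region in ("AG", "F2", "FOC", "PRG"):
            groups = fixture_db.query_by_region(region)
            for t in DistanceType:
                expected = {
                    a.pair
                    for a in fixture_db.assertions
                    if region in a.pair and a.claimed_type is t
                }
                assert {a.pair for a in groups[t]} == expected

    def test_ordering_stable(self, fixture_db):
        groups = fixture_db.query_by_region("AG")
        for t, assertions in groups.items():
            partners = [
                a.region_b if a.region_a == "AG" else a.region_a for a in assertions
            ]
            assert partners == sorted(partners)

    def test_region_without_entries(self, fixture_db):
        groups = fixture_db.query_by_region("CN")
        assert all(not v for v in groups.values())

    def test_unknown_region_raises(self, fixture_db):
        with pytest.raises(UnknownUnitError):
            fixture_db.query_by_region("ZZZ")

    def test_query_by_type(self, fixture_db):
        assert ("AG", "F2") in fixture_db.query_by_type(3)
        for pair in fixture_db.query_by_type(4):
            tiers = {fixture_db.registry.unit(c).is_cortical for c in pair}
            assert tiers == {True, False}  # always cortex <-> subcortical


class TestSqliteStore:
    def test_round_trip(self, fixture_db, tmp_path):
        from connectomatrix.evidence import EvidenceDB

        path = tmp_path / "evidence.sqlite"
        fixture_db.to_sqlite(path)
        again = EvidenceDB.from_sqlite(path, fixture_db.registry)
        assert again.assertions == fixture_db.assertions
        assert set(again.pathways) == set(fixture_db.pathways)
        assert again.publications == fixture_db.publications
        assert again.pathway_regions("SLF") == fixture_db.pathway_regions("SLF")
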
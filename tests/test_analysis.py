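"""Analyses: connectivity maps, era comparison, lesion disconnection
(with a brute-force union oracle), deterministic rendering."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from connectomatrix import (
    CompatibilityError,
    DistanceType,
    Registry,
    UnknownUnitError,
    connectivity_map,
    empty_matrix,
    era_diff,
    lesion_disconnection,
    render_map,
)
from connectomatrix.analysis import plot_map


class TestConnectivityMap:
    def test_ag_long_range_partners_and_pathways(self, pre_dti):
        cmap = connectivity_map(pre_dti, "AG")
        assert "F2" in cmap.partners(3)
        assert cmap.pathway_annotations["F2"] == "SLF"

    def test_projection_partners_are_subcortical(self, registry, pre_dti):
        cmap = connectivity_map(pre_dti, "AG")
        assert cmap.partners(4) <= set(registry.subcortical_codes)

    def test_partner_sets_partition(self, registry, pre_dti):
        """No partner appears under two cortical distance types — the
        coexistence rule guarantees a partition."""
        for region in registry.cortical_codes:
            cmap = connectivity_map(pre_dti, region)
            seen = set()
            for t in (1, 2, 3):
                overlap = cmap.partners(t) & seen
                assert not overlap, (region, t, overlap)
                seen |= cmap.partners(t)

    def test_empty_matrix_empty_map(self, registry):
        cmap = connectivity_map(empty_matrix(registry, "pre_dti"), "AG")
        assert all(not cmap.partners(t) for t in DistanceType)

    def test_unknown_region(self, pre_dti):
        with pytest.raises(UnknownUnitError):
            connectivity_map(pre_dti, "ZZZ")


class TestEraDiff:
    def test_ag_classical_surplus(self, pre_dti, dti):
        d = era_diff(pre_dti, dti, "AG")
        assert {"F3o", "CO", "SMC", "PHa"} <= d.only_in_a[DistanceType.LONG_RANGE]

    def test_f2_classical_surplus(self, pre_dti, dti):
        d = era_diff(pre_dti, dti, "F2")
        assert {"SPL", "OLi", "PT", "CO", "PO", "CGp"} <= d.only_in_a[
            DistanceType.LONG_RANGE
        ]

    def test_antisymmetry(self, pre_dti, dti):
        ab = era_diff(pre_dti, dti, "AG")
        ba = era_diff(dti, pre_dti, "AG")
        for t in DistanceType:
            assert ab.only_in_a[t] == ba.only_in_b[t]
            assert ab.only_in_b[t] == ba.only_in_a[t]

    def test_self_diff_empty(self, pre_dti):
        d = era_diff(pre_dti, pre_dti, "AG")
        assert all(not d.only_in_a[t] and not d.only_in_b[t] for t in DistanceType)

    def test_registry_mismatch_rejected(self, registry, pre_dti):
        other_reg = Registry(registry.units, registry.adjacency_pairs[:-1])
        other = empty_matrix(other_reg, "dti")
        with pytest.raises(CompatibilityError):
            era_diff(pre_dti, other, "AG")


class TestLesionDisconnection:
    def test_single_unit_lesion_reaches_long_range_partner(self, pre_dti):
        report = lesion_disconnection(pre_dti, {"F2"})
        assert "AG" in report.affected(3)

    def test_lesioned_units_excluded_from_affected(self, pre_dti):
        report = lesion_disconnection(pre_dti, {"F2", "AG"})
        for t in DistanceType:
            assert not report.affected(t) & {"F2", "AG"}

    def test_empty_lesion_empty_report(self, pre_dti):
        report = lesion_disconnection(pre_dti, set())
        assert all(not report.affected(t) for t in DistanceType)

    def test_thalamic_only_restricts_projection_output(self, registry, pre_dti):
        full = lesion_disconnection(pre_dti, {"F2", "AG"})
        assert full.affected(4) - set(registry.thalamic_codes)  # STR/PON present
        thal = lesion_disconnection(pre_dti, {"F2", "AG"}, thalamic_only=True)
        assert thal.affected(4) <= set(registry.thalamic_codes)
        assert thal.affected(4)

    def test_provenance_tracks_contributors(self, pre_dti):
        report = lesion_disconnection(pre_dti, {"F2", "AG"})
        assert "F2" in report.provenance[(3, "SPL")]

    def test_depth_two_is_superset(self, pre_dti):
        d1 = lesion_disconnection(pre_dti, {"F2"})
        d2 = lesion_disconnection(pre_dti, {"F2"}, depth=2)
        for t in DistanceType:
            assert d1.affected(t) <= d2.affected(t)
        assert any(d2.affected(t) - d1.affected(t) for t in DistanceType)

    def test_commissural_reported_separately(self, pre_dti):
        report = lesion_disconnection(pre_dti, {"F2"})
        assert report.commissural_affected == {"F2 (contralateral)"}
        for t in DistanceType:
            assert "F2 (contralateral)" not in report.affected(t)

    @settings(
        max_examples=60,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(data=st.data())
    def test_union_property_against_oracle(self, registry, pre_dti, data):
        """report(S) equals the union of single-unit reports over S (minus
        the lesion itself), per the cumulative-representation semantics."""
        lesion = data.draw(
            st.sets(st.sampled_from(registry.cortical_codes), min_size=1, max_size=6)
        )
        report = lesion_disconnection(pre_dti, lesion)
        for t in DistanceType:
            expected = set()
            for unit in lesion:
                expected |= lesion_disconnection(pre_dti, {unit}).affected(t)
            expected -= lesion
            assert report.affected(t) == expected


class TestRendering:
    def test_table_sorted_and_deterministic(self, pre_dti):
        cmap = connectivity_map(pre_dti, "AG")
        out1, out2 = render_map(cmap), render_map(cmap)
        assert out1 == out2
        rows = [
            line for line in out1.splitlines()
            if line.startswith("| ") and "type" not in line and "---" not in line
        ]
        keys = [tuple(line.split("|")[1:3]) for line in rows]
        assert keys == sorted(keys)

    def test_legend_lists_exactly_the_types_present(self, pre_dti):
        report = lesion_disconnection(pre_dti, {"FOC"})
        out = render_map(report)
        present = {int(t) for t in DistanceType if report.affected(t)}
        legend = out.splitlines()[-1]
        for t in (1, 2, 3, 4):
            assert (f"type {t} =" in legend) == (t in present)

    def test_csv_style(self, pre_dti):
        out = render_map(connectivity_map(pre_dti, "AG"), style="csv")
        assert out.splitlines()[0] == "type,partner,pathway"
        assert any(line.startswith("3,F2,SLF") for line in out.splitlines())

    def test_plot_writes_file(self, pre_dti, tmp_path):
        path = tmp_path / "map.svg"
        plot_map(connectivity_map(pre_dti, "AG"), path)
        assert path.stat().st_size > 0
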
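"""Per-plant ranking, marker selection, and table auditing."""

import dataclasses

import pytest

from herbmars import (
    assess_compound,
    audit_dataset,
    rank_compounds,
    select_markers,
)
from herbmars.simulate import SimulationConfig, generate_dataset


def _table(reference, plant_name):
    plant = reference.plant(plant_name)
    assessments = [assess_compound(r) for r in reference.compounds_of(plant)]
    return rank_compounds(plant, assessments)


class TestRanking:
    def test_eucalyptus_order_with_alphabetical_tie_break(self, reference):
        table = _table(reference, "Eucalyptus globulus")
        names = [row.name for row in table]
        # two 8s tie-broken by name: "1,8-cineol" sorts before "α-terpineol"
        assert names == ["1,8-cineol", "α-terpineol", "aromadendrine", "globulol"]
        assert [row.total for row in table] == [8, 8, 7, 6]

    def test_empty_input_yields_empty_table(self, reference):
        table = rank_compounds(reference.plants[0], [])
        assert len(table) == 0

    def test_all_equal_totals_sort_alphabetically(self, reference):
        table = _table(reference, "Warburgia ugandensis")
        twos = [r.name for r in table if r.total == 2]
        assert twos == sorted(twos)

    def test_unsuitable_rows_stay_in_the_table(self, reference):
        table = _table(reference, "Warburgia ugandensis")
        assert len(table) == 7
        assert not any(row.suitable for row in table)


class TestSelection:
    def test_warburgia_yields_no_markers(self, reference):
        assert select_markers(_table(reference, "Warburgia ugandensis")) == []

    def test_mangifera_excludes_epicatechin(self, reference):
        chosen = {m.name for m in select_markers(_table(reference, "Mangifera indica"))}
        assert chosen == {"mangiferin", "catechin", "quercetin", "gallic acid"}

    def test_threshold_above_maximum_selects_nothing(self, reference):
        assert select_markers(_table(reference, "Eucalyptus globulus"), 9) == []

    def test_selection_preserves_rank_order(self, reference):
        chosen = select_markers(_table(reference, "Zingiber officinale"))
        totals = [m.total for m in chosen]
        assert totals == sorted(totals, reverse=True)


class TestAudit:
    def test_reference_audit_surface(self, reference):
        report = audit_dataset(reference.compounds)
        assert report.n_audited == 35 and report.n_skipped == 0

        sums = {f.compound_id for f in report.by_kind("sum_mismatch")}
        assert sums == {"wu-polygodial"}

        deriv = {
            (f.compound_id, f.field)
            for f in report.by_kind("derivation_mismatch")
        }
        # rows whose printed D=1 contradicts a sub-50-ppm concentration,
        # plus the not-determined row printed with C=D=1
        assert ("zo-12-gingerol", "d") in deriv
        assert ("zo-6-shogaol", "d") in deriv
        assert {("ai-mahmoodin", "c"), ("ai-mahmoodin", "d")} <= deriv

        avail = {
            (f.compound_id, f.field)
            for f in report.by_kind("availability_mismatch")
        }
        assert avail == {("zo-zingerone", "f")}

    def test_named_rows_audit_clean_on_the_sum_check(self, reference):
        report = audit_dataset(reference.compounds)
        clean = report.clean_ids(reference.compounds, "sum_mismatch")
        expected_clean = {
            "eg-terpineol", "eg-aromadendrine", "eg-globulol", "eg-cineol",
            "av-aloin-a", "av-aloin-b", "av-aloe-emodin", "av-acemannan",
            "av-m6p", "ac-lupeol", "ac-lupenone", "ac-betulinic-acid",
            "ac-catechin", "mi-mangiferin", "mi-catechin", "mi-epicatechin",
            "mi-gallic-acid", "mi-quercetin", "ai-azadirachtin", "ai-nimbin",
            "zo-6-gingerol", "zo-8-gingerol", "zo-10-gingerol",
            "wu-bemadienolide", "wu-muzigadial", "wu-warbuganal",
            "wu-ugandensidial",
        }
        assert len(expected_clean) == 27
        assert expected_clean <= clean

    def test_records_without_recorded_scores_are_skipped(self, reference):
        stripped = [
            dataclasses.replace(
                r, recorded_components=None, recorded_total=None
            )
            for r in reference.compounds[:3]
        ] + list(reference.compounds[3:])
        report = audit_dataset(stripped)
        assert report.n_skipped == 3
        assert report.n_audited == 32

    def test_consistent_synthetic_dataset_audits_clean(self):
        doc, _ = generate_dataset(SimulationConfig(n_compounds=200, seed=11))
        assert len(audit_dataset(doc.compounds)) == 0

    @pytest.mark.parametrize("seed", [3, 17])
    def test_planted_corruption_recovered_exactly(self, seed):
        doc, truth = generate_dataset(
            SimulationConfig(n_compounds=50, seed=seed, corrupt_k=5)
        )
        report = audit_dataset(doc.compounds)
        assert len(report) == 5
        planted = {
            (e.compound_id, e.field.split(".")[-1])
            for e in truth.corruption_ledger
        }
        found = {(f.compound_id, f.field) for f in report}
        assert found == planted
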
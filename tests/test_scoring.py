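"""The six-component rubric, suitability, roles, and compliance."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbmars import (
    ActivityEvidence,
    CompoundRecord,
    ConcentrationReport,
    MethodListing,
    PackUnit,
    PlantMaterial,
    RegulatoryLimit,
    StandardListing,
    Unit,
    assess_compound,
    assign_role,
    check_regulatory_compliance,
    score_components,
)
from herbmars.simulate import enumerate_component_space, record_for_components
from herbmars.units import PpmValue


def _ppm_record(ppm: float) -> CompoundRecord:
    base = record_for_components(
        dataclasses.replace(enumerate_component_space()[0], c=1)
    )
    return dataclasses.replace(
        base,
        concentration=ConcentrationReport(
            raw_text=f"{ppm} ppm", determined=True, low=ppm, high=ppm,
            unit=Unit.PPM,
        ),
    )


class TestComponents:
    def test_alpha_terpineol_scores_eight(self, by_name):
        cs = score_components(by_name[("Eucalyptus globulus", "α-terpineol")])
        assert cs.as_tuple() == (1, 3, 1, 1, 1, 1)
        assert cs.total == 8

    def test_mannose_6_phosphate_scores_three(self, by_name):
        cs = score_components(by_name[("Aloe vera", "mannose 6-phosphate")])
        assert cs.as_tuple() == (1, 1, 0, 0, 1, 0)
        assert cs.total == 3

    def test_empty_evidence_scores_zero(self):
        rec = CompoundRecord(
            compound_id="x", name="x",
            plant=PlantMaterial(botanical_name="P", part_used=["leaf"]),
        )
        assert score_components(rec).total == 0

    @pytest.mark.parametrize("ppm,c,d", [
        (0.0, 0, 0), (4.99, 0, 0), (5.0, 1, 0), (49.9, 1, 0),
        (50.0, 1, 1), (5000.0, 1, 1),
    ])
    def test_concentration_thresholds_inclusive(self, ppm, c, d):
        cs = score_components(_ppm_record(ppm))
        assert (cs.c, cs.d) == (c, d)

    def test_symptom_count_caps_at_three(self, by_name):
        rec = by_name[("Albizia coriaria", "lupeol")]
        distinct = {
            s for a in rec.activities if a.relevant_to_indication
            for s in a.symptoms_addressed
        }
        assert len(distinct) == 4  # more symptoms than the cap
        assert score_components(rec).b == 3

    def test_symptom_matching_is_case_insensitive(self, by_name):
        rec = by_name[("Warburgia ugandensis", "muzigadial")]
        shouted = dataclasses.replace(
            rec,
            activities=[
                dataclasses.replace(
                    rec.activities[0], symptoms_addressed=["  COUGH "]
                )
            ],
        )
        assert score_components(shouted).b == 1

    def test_oracle_equivalence_over_component_space(self):
        """Scoring a record realizing each admissible vector recovers it."""
        space = enumerate_component_space()
        assert len(space) == 96
        totals = set()
        for expected in space:
            got = score_components(record_for_components(expected))
            assert got == expected
            # independent brute-force total
            brute = sum(
                [expected.a, expected.b, expected.c, expected.d,
                 expected.e, expected.f]
            )
            assert got.total == brute
            totals.add(got.total)
        assert {0, 8} <= totals

    @given(st.sampled_from(enumerate_component_space()))
    def test_adding_evidence_never_lowers_a_component(self, vec):
        base = record_for_components(vec)
        before = score_components(base)
        richer = dataclasses.replace(
            base,
            documented_constituent=True,
            activities=base.activities
            + [ActivityEvidence("extra", ["fatigue", "rash", "nausea"])],
            standards=base.standards
            + [StandardListing("V", "g", 1.0, PackUnit.MG, 9.0)],
            methods=base.methods + [MethodListing("TLC")],
        )
        after = score_components(richer)
        assert all(
            x >= y for x, y in zip(after.as_tuple(), before.as_tuple())
        )
        assert after.total >= before.total

    @given(st.sampled_from(enumerate_component_space()))
    def test_d_never_exceeds_c(self, vec):
        cs = score_components(record_for_components(vec))
        assert cs.d <= cs.c


class TestAssessment:
    def test_suitability_needs_standard_and_method(self, by_name):
        # scores 5 points but has no analytical standard
        epi = assess_compound(by_name[("Mangifera indica", "epicatechin")])
        assert epi.total == 5 and not epi.suitable
        # scores below 5 despite having a standard
        mah = assess_compound(by_name[("Azadirachta indica", "mahmoodin")])
        assert not mah.suitable

    def test_alpha_terpineol_suitable_quantitative(self, by_name):
        a = assess_compound(by_name[("Eucalyptus globulus", "α-terpineol")])
        assert a.suitable and a.role == "quantitative"

    def test_toxic_compound_keeps_score_but_must_screen(self, by_name):
        rec = by_name[("Warburgia ugandensis", "muzigadial")]
        toxic = dataclasses.replace(rec, toxic=True)
        a = assess_compound(toxic)
        assert a.must_screen and a.total == 2 and not a.suitable

    def test_suitable_implies_gates_on_reference(self, reference):
        for rec in reference.compounds:
            a = assess_compound(rec)
            if a.suitable:
                assert a.total >= 5
                assert a.components.e == 1 and a.components.f == 1


class TestRoleAndCompliance:
    @pytest.mark.parametrize("ppm,role", [
        (5000.0, "quantitative"), (50.0, "quantitative"),
        (49.99, "qualitative"), (10.0, "qualitative"), (0.0, "qualitative"),
    ])
    def test_role_thresholds(self, ppm, role):
        assert assign_role(PpmValue(ppm, "point")) == role

    def test_undetermined_role_unassigned(self):
        assert assign_role(None) == "unassigned"

    @pytest.mark.parametrize("measured,limit,verdict", [
        (9.9, 10.0, "compliant"),
        (10.0, 10.0, "compliant"),  # inclusive maximum
        (10.1, 10.0, "non_compliant"),
        (0.5, 0.0, "non_compliant"),  # a zero limit bans any positive level
        (0.0, 0.0, "compliant"),
    ])
    def test_compliance_verdicts(self, measured, limit, verdict):
        lim = RegulatoryLimit("authority", "aloin", limit)
        assert check_regulatory_compliance(measured, lim) == verdict

    def test_aloin_raw_leaf_exceeds_otc_limits(self, by_name):
        a = assess_compound(by_name[("Aloe vera", "aloin A")])
        verdicts = {lim.authority: v for lim, v in a.compliance}
        assert set(verdicts.values()) == {"non_compliant"}
        assert len(verdicts) == 3
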
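"""The modified Herb MaRS rubric.

Each candidate marker is scored 0–8 as the sum of six components:

    A (0/1)  documented constituent of the plant material
    B (0–3)  level of bioactivity evidence = number of distinct indication
             symptoms the compound is documented to treat or alleviate
             (1 symptom → 1, 2 symptoms → 2, 3 or more → 3)
    C (0/1)  reported concentration ≥ 5 ppm
    D (0/1)  reported concentration ≥ 50 ppm  (implies C)
    E (0/1)  an analytical reference standard is commercially listed
    F (0/1)  a published assay method exists

8 marks the most suitable marker.  Suitability additionally demands the
practical gates: a compound is *suitable* iff its total is at least 5 AND a
standard is available AND a method exists (a 5 scored without either cannot
actually be assayed).  Markers are assigned a quantitative role at ≥ 50 ppm
and a qualitative (identity-only) role below; ties at exactly 50 ppm go to
the quantitative arm, consistent with component D.  Toxic compounds keep
their computed score but are flagged ``must_screen`` — screening them is
mandatory regardless of rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .evidence import (
    CompoundRecord,
    RegulatoryLimit,
    normalize_symptom,
    validate_record,
)
from .units import UNDETERMINED, PpmValue, to_ppm

__all__ = [
    "ComponentScores",
    "MarkerAssessment",
    "SUITABILITY_THRESHOLD",
    "QUANTITATIVE_PPM",
    "LOW_PPM",
    "score_components",
    "assess_compound",
    "assign_role",
    "check_regulatory_compliance",
]

#: Minimum total for a marker to be considered suitable.
SUITABILITY_THRESHOLD = 5
#: Concentration gate for component C (1 point).
LOW_PPM = 5.0
#: Concentration gate for component D (2nd point) and the quantitative role.
QUANTITATIVE_PPM = 50.0


@dataclass(frozen=True)
class ComponentScores:
    """The six rubric components; ``total`` is always their sum."""

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d + self.e + self.f

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


@dataclass
class MarkerAssessment:
    """Scores plus the derived regulatory-facing verdicts for one compound."""

    compound_id: str
    name: str
    components: ComponentScores
    ppm: Optional[PpmValue]
    suitable: bool
    role: str  # "quantitative" | "qualitative" | "unassigned"
    must_screen: bool
    compliance: list[tuple[RegulatoryLimit, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.components.total


class InvalidRecordError(ValueError):
    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


def _count_covered_symptoms(record: CompoundRecord) -> int:
    covered: set[str] = set()
    for act in record.activities:
        if act.relevant_to_indication:
            covered.update(normalize_symptom(s) for s in act.symptoms_addressed)
    return len(covered)


def score_components(record: CompoundRecord, *, validate: bool = True) -> ComponentScores:
    """Compute components A–F from the record's evidence.

    The concentration components derive from the ppm-normalized report:
    undetermined → C=D=0; ≥ 5 ppm earns C; ≥ 50 ppm earns D as well.
    """
    if validate:
        violations = validate_record(record)
        if violations:
            raise InvalidRecordError(violations)

    a = 1 if record.documented_constituent else 0
    b = min(3, _count_covered_symptoms(record))

    ppm = to_ppm(record.concentration)
    if ppm is UNDETERMINED:
        c = d = 0
    else:
        c = 1 if ppm.value >= LOW_PPM else 0
        d = 1 if ppm.value >= QUANTITATIVE_PPM else 0

    e = 1 if record.standards else 0
    f = 1 if record.methods else 0
    return ComponentScores(a=a, b=b, c=c, d=d, e=e, f=f)


def assign_role(ppm: Optional[PpmValue]) -> str:
    """Analytical role from the normalized concentration.

    Undetermined → "unassigned"; ≥ 50 ppm → "quantitative" (the marker is
    abundant enough to be assayed); below → "qualitative" (identity check
    only).
    """
    if ppm is UNDETERMINED:
        return "unassigned"
    return "quantitative" if ppm.value >= QUANTITATIVE_PPM else "qualitative"


def check_regulatory_compliance(measured_ppm: float, limit: RegulatoryLimit) -> str:
    """Verdict of one measurement against one maximum limit.

    The limit is an inclusive maximum; a 0 ppm limit therefore makes any
    positive measurement non-compliant.
    """
    if measured_ppm < 0:
        raise ValueError("measured_ppm must be non-negative")
    return "compliant" if measured_ppm <= limit.limit_ppm else "non_compliant"


def assess_compound(record: CompoundRecord, *, validate: bool = True) -> MarkerAssessment:
    """Full per-compound assessment: scores, suitability, role, compliance.

    Suitability = total ≥ 5 AND standard available (E=1) AND method available
    (F=1).  Compliance verdicts are evaluated against the record's own
    reported concentration; with no determined concentration the verdict is
    "not_evaluable".
    """
    components = score_components(record, validate=validate)
    ppm = to_ppm(record.concentration)

    suitable = (
        components.total >= SUITABILITY_THRESHOLD
        and components.e == 1
        and components.f == 1
    )

    compliance: list[tuple[RegulatoryLimit, str]] = []
    for limit in record.negative_marker_limits:
        if ppm is UNDETERMINED:
            compliance.append((limit, "not_evaluable"))
        else:
            compliance.append((limit, check_regulatory_compliance(ppm.value, limit)))

    return MarkerAssessment(
        compound_id=record.compound_id,
        name=record.name,
        components=components,
        ppm=ppm,
        suitable=suitable,
        role=assign_role(ppm),
        must_screen=record.toxic,
        compliance=compliance,
    )
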
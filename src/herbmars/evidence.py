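"""Domain types for chemical-marker evidence dossiers.

A *marker* is a constituent compound measured to authenticate and standardize
an herbal raw material.  Everything the ranking rubric consumes about a
candidate marker — the plant and its labelled indications, documented
bioactivities and the symptoms they address, literature concentration
reports, vendor listings of analytical reference standards, published assay
methods, toxicity flags and regulatory limits — is modelled here as plain,
serializable dataclasses.

Validation is deliberately non-throwing: :func:`validate_record` inspects a
record and returns a list of human-readable violations (empty when the record
is internally consistent), so that batch imports can report every problem in
one pass instead of failing on the first.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .scoring import ComponentScores

__all__ = [
    "Unit",
    "PackUnit",
    "PlantSource",
    "IndicationProfile",
    "PlantMaterial",
    "ActivityEvidence",
    "ConcentrationReport",
    "StandardListing",
    "MethodListing",
    "RegulatoryLimit",
    "CompoundRecord",
    "normalize_symptom",
    "validate_record",
    "load_reference_dataset",
]


class Unit(str, Enum):
    """Concentration units occurring in literature reports."""

    PERCENT_W_W = "percent_w_w"
    MG_PER_G = "mg_per_g"
    PPM = "ppm"


class PackUnit(str, Enum):
    """Denomination of a commercial reference-standard pack."""

    MG = "mg"
    ML = "mL"
    G = "g"


class PlantSource(str, Enum):
    WILD = "wild"
    CULTIVATED = "cultivated"
    BOTH = "both"


def normalize_symptom(text: str) -> str:
    """Canonical form used for symptom comparison: NFKC, trimmed, casefolded.

    No stemming or synonym expansion is applied; matching stays deterministic
    and auditable.
    """
    return unicodedata.normalize("NFKC", text).strip().casefold()


@dataclass
class IndicationProfile:
    """One labelled indication of a product and the symptoms it covers."""

    condition: str
    symptoms: list[str] = field(default_factory=list)


@dataclass
class PlantMaterial:
    """An herbal raw material and the therapeutic claims made on products."""

    botanical_name: str
    family: str = ""
    source: PlantSource = PlantSource.WILD
    part_used: list[str] = field(default_factory=list)
    dosage_forms: list[str] = field(default_factory=list)
    indications: list[IndicationProfile] = field(default_factory=list)

    def symptom_universe(self) -> set[str]:
        """Normalized union of symptoms over all indications."""
        return {
            normalize_symptom(s)
            for ind in self.indications
            for s in ind.symptoms
        }


@dataclass
class ActivityEvidence:
    """A documented bioactivity of a compound and the symptoms it addresses."""

    activity_name: str
    symptoms_addressed: list[str] = field(default_factory=list)
    relevant_to_indication: bool = True
    mechanism: str = ""
    citations: list[str] = field(default_factory=list)


@dataclass
class ConcentrationReport:
    """A literature concentration report, kept verbatim plus parsed fields.

    ``determined=False`` encodes "ND" (never measured); in that case the
    numeric fields and unit are absent.  Single values are stored with
    ``low == high``.  ``basis`` is the matrix the report refers to (essential
    oil, gel, stem bark, ...) and is carried as metadata only — values are
    never rescaled between matrices.
    """

    raw_text: str
    determined: bool = False
    low: Optional[float] = None
    high: Optional[float] = None
    unit: Optional[Unit] = None
    basis: str = ""

    @classmethod
    def not_determined(cls, raw_text: str = "ND") -> "ConcentrationReport":
        return cls(raw_text=raw_text, determined=False)


@dataclass
class StandardListing:
    """One vendor listing of an analytical reference standard."""

    vendor: str
    grade: str
    pack_value: float
    pack_unit: PackUnit
    price_eur: float


@dataclass
class MethodListing:
    """One published assay method applicable to the compound."""

    technique: str
    matrix: str = ""
    citation: str = ""


@dataclass
class RegulatoryLimit:
    """A maximum-concentration limit set by a regulatory authority.

    A 0 ppm limit bans the analyte outright: any positive measurement is
    non-compliant.
    """

    authority: str
    analyte: str
    limit_ppm: float
    direction: str = "maximum"


@dataclass
class CompoundRecord:
    """The full evidence dossier for one candidate marker in one plant context.

    ``documented_constituent`` is recorded explicitly (not derived from the
    activities list): a compound can be a documented constituent of the
    material with no individually studied bioactivity, and the two facts are
    scored differently.  ``recorded_components``/``recorded_total`` hold
    scores as printed in a source table, for auditing only — they are never
    used by the scoring path.
    """

    compound_id: str
    name: str
    plant: PlantMaterial
    documented_constituent: bool = False
    activities: list[ActivityEvidence] = field(default_factory=list)
    concentration: ConcentrationReport = field(
        default_factory=ConcentrationReport.not_determined
    )
    standards: list[StandardListing] = field(default_factory=list)
    methods: list[MethodListing] = field(default_factory=list)
    toxic: bool = False
    negative_marker_limits: list[RegulatoryLimit] = field(default_factory=list)
    recorded_components: Optional["ComponentScores"] = None
    recorded_total: Optional[int] = None


_COMPONENT_RANGES = {"a": (0, 1), "b": (0, 3), "c": (0, 1), "d": (0, 1),
                     "e": (0, 1), "f": (0, 1)}


def validate_record(record: CompoundRecord) -> list[str]:
    """Check every type invariant; return one message per violation.

    Returns an empty list iff the record is valid.  Never raises on bad
    content — missing or malformed fields each contribute a violation naming
    the offending field.
    """
    v: list[str] = []

    if not getattr(record, "compound_id", ""):
        v.append("compound_id: must be non-empty")
    if not getattr(record, "name", ""):
        v.append("name: must be non-empty")

    plant = getattr(record, "plant", None)
    if plant is None:
        v.append("plant: missing")
    else:
        if not plant.botanical_name:
            v.append("plant.botanical_name: must be non-empty")
        if not plant.part_used:
            v.append("plant.part_used: at least one part required")
        for ind in plant.indications:
            seen = {normalize_symptom(s) for s in ind.symptoms}
            if len(seen) != len(ind.symptoms):
                v.append(
                    f"plant.indications[{ind.condition!r}].symptoms: "
                    "must be deduplicated"
                )

    universe = plant.symptom_universe() if plant is not None else set()
    for i, act in enumerate(record.activities):
        if act.relevant_to_indication:
            stray = {
                normalize_symptom(s) for s in act.symptoms_addressed
            } - universe
            if stray:
                v.append(
                    f"activities[{i}].symptoms_addressed: not among the "
                    f"plant's indication symptoms: {sorted(stray)}"
                )

    conc = record.concentration
    if conc is None:
        v.append("concentration: missing")
    elif conc.determined:
        if conc.low is None:
            v.append("concentration.low: required when determined")
        if conc.high is None:
            v.append("concentration.high: required when determined")
        if conc.unit is None:
            v.append("concentration.unit: required when determined")
        if conc.low is not None and conc.low < 0:
            v.append("concentration.low: must be non-negative")
        if conc.low is not None and conc.high is not None and conc.low > conc.high:
            v.append("concentration.low: must not exceed concentration.high")
    else:
        for name_ in ("low", "high", "unit"):
            if getattr(conc, name_) is not None:
                v.append(
                    f"concentration.{name_}: must be absent when not determined"
                )

    for i, std in enumerate(record.standards):
        if std.pack_value is None or std.pack_value <= 0:
            v.append(f"standards[{i}].pack_value: must be positive")
        if std.price_eur is None or std.price_eur <= 0:
            v.append(f"standards[{i}].price_eur: must be positive")
        if not isinstance(std.pack_unit, PackUnit):
            v.append(f"standards[{i}].pack_unit: invalid denomination")

    for i, m in enumerate(record.methods):
        if not m.technique:
            v.append(f"methods[{i}].technique: must be non-empty")

    for i, lim in enumerate(record.negative_marker_limits):
        if lim.limit_ppm is None or lim.limit_ppm < 0:
            v.append(
                f"negative_marker_limits[{i}].limit_ppm: must be non-negative"
            )

    rc = record.recorded_components
    if rc is not None:
        for name_, (lo, hi) in _COMPONENT_RANGES.items():
            val = getattr(rc, name_, None)
            if val is None or not (lo <= val <= hi):
                v.append(
                    f"recorded_components.{name_}: must be in [{lo}, {hi}]"
                )
        if getattr(rc, "c", 1) == 0 and getattr(rc, "d", 0) == 1:
            v.append("recorded_components.d: cannot exceed recorded_components.c")

    rt = record.recorded_total
    if rt is not None and not (0 <= rt <= 8):
        v.append("recorded_total: must be in [0, 8]")

    return v


def load_reference_dataset():
    """Load the packaged study dataset (seven Ugandan medicinal plants,
    35 candidate-marker dossiers, anthraquinone regulatory limits).

    Returns a :class:`herbmars.io.DatasetDocument`.
    """
    from importlib.resources import files

    from .io import dataset_from_dict
    import json

    text = files("herbmars.fixtures").joinpath("herbmars_tables.json").read_text(
        encoding="utf-8"
    )
    return dataset_from_dict(json.loads(text))
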
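"""Synthetic evidence datasets with known ground-truth scores.

The generator emulates the *structure* of a scored marker table: each
synthetic compound gets a constituent flag, a symptom-coverage level, a
concentration report (drawn log-uniformly in ppm, then re-expressed in a
random unit as a point value or a symmetric range whose midpoint reproduces
the drawn ppm exactly), and standard/method listings — so the rubric score
of every record is known by construction.  Default probabilities mirror the
empirical frequencies of the packaged study table (e.g. nearly all rows are
documented constituents, ~70% of concentrations are determined).

Optionally, ``corrupt_k`` records have their *recorded* scores perturbed
after the fact, with a ledger of exactly what was changed; the auditor must
recover the ledger one-for-one.  Components are corrupted together with the
recorded total (keeping the sum consistent) so that each planted corruption
yields exactly one finding of a predictable kind.

:func:`enumerate_component_space` provides the exhaustive 96-vector oracle
for the rubric (2·4·3·2·2 admissible component combinations once D ≤ C is
imposed), together with a record realizing each vector.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .evidence import (
    ActivityEvidence,
    CompoundRecord,
    ConcentrationReport,
    IndicationProfile,
    MethodListing,
    PackUnit,
    PlantMaterial,
    PlantSource,
    StandardListing,
    Unit,
)
from .io import DatasetDocument
from .scoring import ComponentScores
from .units import PPM_PER_UNIT, format_concentration

__all__ = [
    "SimulationConfig",
    "CorruptionEntry",
    "GroundTruth",
    "generate_dataset",
    "enumerate_component_space",
    "record_for_components",
]

#: Symptom pool of the synthetic plant; six suffice for any coverage level.
_SYMPTOMS = ["cough", "fever", "headache", "nausea", "rash", "fatigue"]


def _synthetic_plant() -> PlantMaterial:
    return PlantMaterial(
        botanical_name="Simulatum officinale",
        family="Simulataceae",
        source=PlantSource.CULTIVATED,
        part_used=["leaf"],
        dosage_forms=["syrup"],
        indications=[
            IndicationProfile(condition="synthetic syndrome", symptoms=list(_SYMPTOMS))
        ],
    )


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study table's structure."""

    n_compounds: int = 100
    seed: int = 0
    p_constituent: float = 0.95
    symptom_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.10, 1: 0.25, 2: 0.25, 3: 0.40}
    )
    p_concentration_determined: float = 0.70
    ppm_log_range: tuple[float, float] = (0.0, 6.0)  # log10 ppm
    p_standard: float = 0.75
    p_method: float = 0.80
    p_toxic: float = 0.10
    corrupt_k: int = 0

    def validate(self) -> None:
        probs = [
            self.p_constituent, self.p_concentration_determined,
            self.p_standard, self.p_method, self.p_toxic,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        weights = self.symptom_count_distribution
        if set(weights) != {0, 1, 2, 3} or abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError(
                "symptom_count_distribution must map {0,1,2,3} to weights summing to 1"
            )
        if not self.ppm_log_range[0] < self.ppm_log_range[1]:
            raise ValueError("ppm_log_range low must be below high")
        if self.corrupt_k < 0 or self.corrupt_k > self.n_compounds:
            raise ValueError("corrupt_k must be in [0, n_compounds]")
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")


@dataclass(frozen=True)
class CorruptionEntry:
    compound_id: str
    field: str  # "recorded_total" or "recorded_components.<a..f>"
    original: int
    corrupted: int


@dataclass
class GroundTruth:
    """Expected components per compound plus the planted-corruption ledger."""

    components: dict[str, ComponentScores] = field(default_factory=dict)
    corruption_ledger: list[CorruptionEntry] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "components": {
                cid: dict(zip("abcdef", cs.as_tuple()))
                for cid, cs in self.components.items()
            },
            "corruption_ledger": [
                {
                    "compound_id": e.compound_id,
                    "field": e.field,
                    "original": e.original,
                    "corrupted": e.corrupted,
                }
                for e in self.corruption_ledger
            ],
        }


def _draw_concentration(rng: random.Random, ppm: float) -> ConcentrationReport:
    """Re-express a drawn ppm in a random unit, as a point or symmetric range."""
    unit = rng.choice(list(Unit))
    value = ppm / PPM_PER_UNIT[unit]
    if rng.random() < 0.5:
        low = high = value
    else:
        delta = rng.uniform(0.05, 0.5)
        low, high = value * (1 - delta), value * (1 + delta)
    report = ConcentrationReport(
        raw_text="", determined=True, low=low, high=high, unit=unit,
        basis="leaf",
    )
    return replace(report, raw_text=format_concentration(report))


def _make_record(
    rng: random.Random, index: int, plant: PlantMaterial, cfg: SimulationConfig
) -> tuple[CompoundRecord, ComponentScores]:
    cid = f"sim-{index:04d}"
    a = 1 if rng.random() < cfg.p_constituent else 0

    levels = sorted(cfg.symptom_count_distribution)
    weights = [cfg.symptom_count_distribution[k] for k in levels]
    level = rng.choices(levels, weights=weights)[0]
    activities = []
    if level > 0:
        symptoms = rng.sample(_SYMPTOMS, level)
        activities.append(
            ActivityEvidence(
                activity_name="synthetic activity",
                symptoms_addressed=symptoms,
                relevant_to_indication=True,
                mechanism="synthetic mechanism",
                citations=[f"SYN{index}"],
            )
        )
    # occasional irrelevant activity; must never contribute to B
    if rng.random() < 0.2:
        activities.append(
            ActivityEvidence(
                activity_name="unrelated activity",
                symptoms_addressed=["unrelated symptom"],
                relevant_to_indication=False,
            )
        )

    if rng.random() < cfg.p_concentration_determined:
        ppm = 10.0 ** rng.uniform(*cfg.ppm_log_range)
        concentration = _draw_concentration(rng, ppm)
        c = 1 if ppm >= 5.0 else 0
        d = 1 if ppm >= 50.0 else 0
    else:
        concentration = ConcentrationReport.not_determined()
        c = d = 0

    standards = []
    if rng.random() < cfg.p_standard:
        standards.append(
            StandardListing(
                vendor="SynthChem",
                grade="analytical standard",
                pack_value=rng.choice([1.0, 5.0, 10.0, 100.0]),
                pack_unit=rng.choice([PackUnit.MG, PackUnit.ML]),
                price_eur=round(rng.uniform(10.0, 600.0), 2),
            )
        )
    methods = []
    if rng.random() < cfg.p_method:
        methods.append(
            MethodListing(technique="HPLC-UV", matrix="leaf", citation=f"SYN{index}m")
        )

    truth = ComponentScores(
        a=a, b=level, c=c, d=d, e=1 if standards else 0, f=1 if methods else 0
    )
    record = CompoundRecord(
        compound_id=cid,
        name=f"simulin {index:04d}",
        plant=plant,
        documented_constituent=bool(a),
        activities=activities,
        concentration=concentration,
        standards=standards,
        methods=methods,
        toxic=rng.random() < cfg.p_toxic,
        recorded_components=truth,
        recorded_total=truth.total,
    )
    return record, truth


def _corrupt(rng: random.Random, rec: CompoundRecord) -> CorruptionEntry:
    """Perturb one recorded field in place; return the ledger entry.

    Component corruptions adjust the recorded total too, so the sum check
    stays clean and the single finding is a derivation/availability
    mismatch; total corruptions leave components alone and trip the sum
    check only.  Moves that would make the recorded vector invalid
    (component out of range, D > C) are never proposed.
    """
    rc = rec.recorded_components
    moves: list[tuple[str, int]] = [("recorded_total", 0)]
    if rc.a in (0, 1):
        moves.append(("a", 1 - rc.a))
    moves.append(("b", rng.choice([x for x in range(4) if x != rc.b])))
    if not (rc.c == 1 and rc.d == 1):  # flipping c to 0 must not strand d=1
        moves.append(("c", 1 - rc.c))
    if rc.d == 1 or rc.c == 1:  # d may rise only under c=1
        moves.append(("d", 1 - rc.d))
    moves.append(("e", 1 - rc.e))
    moves.append(("f", 1 - rc.f))

    field_name, new_value = rng.choice(moves)
    if field_name == "recorded_total":
        old = rec.recorded_total
        delta = rng.choice([-1, 1])
        new = old + delta
        if not (0 <= new <= 8):
            new = old - delta
        rec.recorded_total = new
        return CorruptionEntry(rec.compound_id, "recorded_total", old, new)

    old = getattr(rc, field_name)
    new_rc = replace(rc, **{field_name: new_value})
    rec.recorded_components = new_rc
    rec.recorded_total = new_rc.total  # keep the printed sum consistent
    return CorruptionEntry(
        rec.compound_id, f"recorded_components.{field_name}", old, new_value
    )


def generate_dataset(
    config: Optional[SimulationConfig] = None, **overrides
) -> tuple[DatasetDocument, GroundTruth]:
    """Generate a dataset and its ground truth; deterministic per seed."""
    cfg = config if config is not None else SimulationConfig(**overrides)
    cfg.validate()
    rng = random.Random(cfg.seed)
    plant = _synthetic_plant()

    truth = GroundTruth()
    compounds: list[CompoundRecord] = []
    for i in range(cfg.n_compounds):
        rec, cs = _make_record(rng, i, plant, cfg)
        compounds.append(rec)
        truth.components[rec.compound_id] = cs

    if cfg.corrupt_k:
        victims = rng.sample(range(cfg.n_compounds), cfg.corrupt_k)
        for i in sorted(victims):
            truth.corruption_ledger.append(_corrupt(rng, compounds[i]))

    doc = DatasetDocument(plants=[plant], compounds=compounds)
    return doc, truth


# --------------------------------------------------------------------------
# exhaustive component-space oracle

def record_for_components(components: ComponentScores) -> CompoundRecord:
    """A minimal record whose evidence realizes the given component vector.

    C/D are realized by a fixed concentration per (c, d) arm: undetermined
    for (0,0), 10 ppm for (1,0), 100 ppm for (1,1).
    """
    plant = _synthetic_plant()
    conc = {
        (0, 0): ConcentrationReport.not_determined(),
        (1, 0): ConcentrationReport(
            raw_text="10 ppm of leaf", determined=True, low=10.0, high=10.0,
            unit=Unit.PPM, basis="leaf",
        ),
        (1, 1): ConcentrationReport(
            raw_text="100 ppm of leaf", determined=True, low=100.0, high=100.0,
            unit=Unit.PPM, basis="leaf",
        ),
    }[(components.c, components.d)]
    return CompoundRecord(
        compound_id=f"oracle-{''.join(map(str, components.as_tuple()))}",
        name="oracle compound",
        plant=plant,
        documented_constituent=bool(components.a),
        activities=(
            [
                ActivityEvidence(
                    activity_name="oracle activity",
                    symptoms_addressed=_SYMPTOMS[: components.b],
                )
            ]
            if components.b
            else []
        ),
        concentration=conc,
        standards=(
            [
                StandardListing(
                    vendor="SynthChem", grade="analytical standard",
                    pack_value=10.0, pack_unit=PackUnit.MG, price_eur=100.0,
                )
            ]
            if components.e
            else []
        ),
        methods=[MethodListing(technique="HPLC-UV")] if components.f else [],
    )


def enumerate_component_space() -> list[ComponentScores]:
    """All 96 admissible component vectors (a, b, (c,d) with d ≤ c, e, f)."""
    out = []
    for a in (0, 1):
        for b in (0, 1, 2, 3):
            for c, d in ((0, 0), (1, 0), (1, 1)):
                for e in (0, 1):
                    for f in (0, 1):
                        out.append(ComponentScores(a=a, b=b, c=c, d=d, e=e, f=f))
    return out
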
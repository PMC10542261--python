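"""Dataset documents: JSON (canonical), YAML and CSV dialects, and reports.

A :class:`DatasetDocument` bundles plants, compound dossiers and a catalog of
regulatory limits under a schema version.  JSON is the canonical on-disk
form (schema published as ``fixtures/dataset.schema.json``); YAML is a
convenience mirror of the same tree; the CSV dialect is a *directory* of
companion tables (plants, indications, compounds, activities, standards,
methods, limits, meta) with list-valued fields semicolon-joined.  All three
round-trip losslessly: ``read_dataset(write_dataset(doc)) == doc``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .costing import CostSummary, iter_unit_costs
from .evidence import (
    ActivityEvidence,
    CompoundRecord,
    ConcentrationReport,
    IndicationProfile,
    MethodListing,
    PackUnit,
    PlantMaterial,
    PlantSource,
    RegulatoryLimit,
    StandardListing,
    Unit,
    validate_record,
)
from .ranking import AuditReport, RankedMarkerTable
from .scoring import ComponentScores

__all__ = [
    "SCHEMA_VERSION",
    "DatasetDocument",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "dataset_from_dict",
    "dataset_to_dict",
    "render_ranking_report",
]

SCHEMA_VERSION = "1.0"
_LIST_SEP = ";"


class DatasetValidationError(ValueError):
    """Carries *every* violation found in a document, not just the first."""

    def __init__(self, violations: list[str]):
        super().__init__(
            "invalid dataset:\n" + "\n".join(f"  - {v}" for v in violations)
        )
        self.violations = violations


@dataclass
class DatasetDocument:
    schema_version: str = SCHEMA_VERSION
    plants: list[PlantMaterial] = field(default_factory=list)
    compounds: list[CompoundRecord] = field(default_factory=list)
    limits: list[RegulatoryLimit] = field(default_factory=list)

    def plant(self, botanical_name: str) -> PlantMaterial:
        for p in self.plants:
            if p.botanical_name == botanical_name:
                return p
        raise KeyError(botanical_name)

    def compounds_of(self, plant: PlantMaterial) -> list[CompoundRecord]:
        return [
            c for c in self.compounds
            if c.plant.botanical_name == plant.botanical_name
        ]

    def validate(self) -> list[str]:
        violations: list[str] = []
        seen_ids: set[str] = set()
        plant_names = {p.botanical_name for p in self.plants}
        for rec in self.compounds:
            if rec.compound_id in seen_ids:
                violations.append(
                    f"compound_id {rec.compound_id!r}: duplicated in dataset"
                )
            seen_ids.add(rec.compound_id)
            if rec.plant.botanical_name not in plant_names:
                violations.append(
                    f"{rec.compound_id}: plant {rec.plant.botanical_name!r} "
                    "not in document's plants"
                )
            violations.extend(
                f"{rec.compound_id}: {v}" for v in validate_record(rec)
            )
        return violations


# --------------------------------------------------------------------------
# dict codecs (shared by JSON and YAML)

def _conc_to_dict(c: ConcentrationReport) -> dict:
    return {
        "raw_text": c.raw_text,
        "determined": c.determined,
        "low": c.low,
        "high": c.high,
        "unit": c.unit.value if c.unit is not None else None,
        "basis": c.basis,
    }


def _conc_from_dict(d: dict) -> ConcentrationReport:
    return ConcentrationReport(
        raw_text=d.get("raw_text", ""),
        determined=bool(d.get("determined", False)),
        low=d.get("low"),
        high=d.get("high"),
        unit=Unit(d["unit"]) if d.get("unit") else None,
        basis=d.get("basis", ""),
    )


def _limit_to_dict(lim: RegulatoryLimit) -> dict:
    return {
        "authority": lim.authority,
        "analyte": lim.analyte,
        "limit_ppm": lim.limit_ppm,
        "direction": lim.direction,
    }


def _limit_from_dict(d: dict) -> RegulatoryLimit:
    return RegulatoryLimit(
        authority=d["authority"],
        analyte=d["analyte"],
        limit_ppm=float(d["limit_ppm"]),
        direction=d.get("direction", "maximum"),
    )


def _plant_to_dict(p: PlantMaterial) -> dict:
    return {
        "botanical_name": p.botanical_name,
        "family": p.family,
        "source": p.source.value,
        "part_used": list(p.part_used),
        "dosage_forms": list(p.dosage_forms),
        "indications": [
            {"condition": i.condition, "symptoms": list(i.symptoms)}
            for i in p.indications
        ],
    }


def _plant_from_dict(d: dict) -> PlantMaterial:
    return PlantMaterial(
        botanical_name=d["botanical_name"],
        family=d.get("family", ""),
        source=PlantSource(d.get("source", "wild")),
        part_used=list(d.get("part_used", [])),
        dosage_forms=list(d.get("dosage_forms", [])),
        indications=[
            IndicationProfile(
                condition=i["condition"], symptoms=list(i.get("symptoms", []))
            )
            for i in d.get("indications", [])
        ],
    )


def _compound_to_dict(rec: CompoundRecord) -> dict:
    rc = rec.recorded_components
    return {
        "compound_id": rec.compound_id,
        "name": rec.name,
        "plant": rec.plant.botanical_name,
        "documented_constituent": rec.documented_constituent,
        "activities": [
            {
                "activity_name": a.activity_name,
                "symptoms_addressed": list(a.symptoms_addressed),
                "relevant_to_indication": a.relevant_to_indication,
                "mechanism": a.mechanism,
                "citations": list(a.citations),
            }
            for a in rec.activities
        ],
        "concentration": _conc_to_dict(rec.concentration),
        "standards": [
            {
                "vendor": s.vendor,
                "grade": s.grade,
                "pack_value": s.pack_value,
                "pack_unit": s.pack_unit.value,
                "price_eur": s.price_eur,
            }
            for s in rec.standards
        ],
        "methods": [
            {"technique": m.technique, "matrix": m.matrix, "citation": m.citation}
            for m in rec.methods
        ],
        "toxic": rec.toxic,
        "negative_marker_limits": [
            _limit_to_dict(lim) for lim in rec.negative_marker_limits
        ],
        "recorded_components": (
            None if rc is None
            else {"a": rc.a, "b": rc.b, "c": rc.c, "d": rc.d, "e": rc.e, "f": rc.f}
        ),
        "recorded_total": rec.recorded_total,
    }


def _compound_from_dict(d: dict, plants: dict[str, PlantMaterial]) -> CompoundRecord:
    rc = d.get("recorded_components")
    return CompoundRecord(
        compound_id=d["compound_id"],
        name=d["name"],
        plant=plants[d["plant"]],
        documented_constituent=bool(d.get("documented_constituent", False)),
        activities=[
            ActivityEvidence(
                activity_name=a["activity_name"],
                symptoms_addressed=list(a.get("symptoms_addressed", [])),
                relevant_to_indication=bool(a.get("relevant_to_indication", True)),
                mechanism=a.get("mechanism", ""),
                citations=list(a.get("citations", [])),
            )
            for a in d.get("activities", [])
        ],
        concentration=_conc_from_dict(d.get("concentration", {})),
        standards=[
            StandardListing(
                vendor=s["vendor"],
                grade=s.get("grade", ""),
                pack_value=float(s["pack_value"]),
                pack_unit=PackUnit(s["pack_unit"]),
                price_eur=float(s["price_eur"]),
            )
            for s in d.get("standards", [])
        ],
        methods=[
            MethodListing(
                technique=m["technique"],
                matrix=m.get("matrix", ""),
                citation=m.get("citation", ""),
            )
            for m in d.get("methods", [])
        ],
        toxic=bool(d.get("toxic", False)),
        negative_marker_limits=[
            _limit_from_dict(x) for x in d.get("negative_marker_limits", [])
        ],
        recorded_components=(
            None if rc is None else ComponentScores(**{k: int(rc[k]) for k in "abcdef"})
        ),
        recorded_total=(
            None if d.get("recorded_total") is None else int(d["recorded_total"])
        ),
    )


def dataset_to_dict(doc: DatasetDocument) -> dict:
    return {
        "schema_version": doc.schema_version,
        "plants": [_plant_to_dict(p) for p in doc.plants],
        "compounds": [_compound_to_dict(c) for c in doc.compounds],
        "limits": [_limit_to_dict(lim) for lim in doc.limits],
    }


def dataset_from_dict(data: dict) -> DatasetDocument:
    plants = [_plant_from_dict(p) for p in data.get("plants", [])]
    by_name = {p.botanical_name: p for p in plants}
    compounds = []
    missing: list[str] = []
    for cd in data.get("compounds", []):
        if cd.get("plant") not in by_name:
            missing.append(
                f"{cd.get('compound_id', '?')}: plant {cd.get('plant')!r} "
                "not in document's plants"
            )
            continue
        compounds.append(_compound_from_dict(cd, by_name))
    doc = DatasetDocument(
        schema_version=data.get("schema_version", SCHEMA_VERSION),
        plants=plants,
        compounds=compounds,
        limits=[_limit_from_dict(x) for x in data.get("limits", [])],
    )
    violations = missing + doc.validate()
    if violations:
        raise DatasetValidationError(violations)
    return doc


# --------------------------------------------------------------------------
# CSV dialect: a directory of companion tables

def _join(items: list[str]) -> str:
    for item in items:
        if _LIST_SEP in item:
            raise ValueError(
                f"list item {item!r} contains the reserved separator {_LIST_SEP!r}"
            )
    return _LIST_SEP.join(items)


def _split(cell: str) -> list[str]:
    return cell.split(_LIST_SEP) if cell else []


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell != "" else None


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_table(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([_fmt(v) for v in row])


def _read_table(path: Path) -> list[dict[str, str]]:
    with path.open("r", newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _write_csv_dir(doc: DatasetDocument, root: Path) -> None:
    root.mkdir(parents=True, exist_ok=True)
    _write_table(root / "meta.csv", ["key", "value"],
                 [["schema_version", doc.schema_version]])
    _write_table(
        root / "plants.csv",
        ["botanical_name", "family", "source", "part_used", "dosage_forms"],
        [
            [p.botanical_name, p.family, p.source.value,
             _join(p.part_used), _join(p.dosage_forms)]
            for p in doc.plants
        ],
    )
    _write_table(
        root / "indications.csv",
        ["plant", "condition", "symptoms"],
        [
            [p.botanical_name, ind.condition, _join(ind.symptoms)]
            for p in doc.plants
            for ind in p.indications
        ],
    )
    _write_table(
        root / "compounds.csv",
        [
            "compound_id", "name", "plant", "documented_constituent",
            "conc_raw_text", "conc_determined", "conc_low", "conc_high",
            "conc_unit", "conc_basis", "toxic",
            "recorded_a", "recorded_b", "recorded_c", "recorded_d",
            "recorded_e", "recorded_f", "recorded_total",
        ],
        [
            [
                c.compound_id, c.name, c.plant.botanical_name,
                c.documented_constituent,
                c.concentration.raw_text, c.concentration.determined,
                c.concentration.low, c.concentration.high,
                c.concentration.unit.value if c.concentration.unit else None,
                c.concentration.basis, c.toxic,
            ]
            + (
                [None] * 6 if c.recorded_components is None
                else list(c.recorded_components.as_tuple())
            )
            + [c.recorded_total]
            for c in doc.compounds
        ],
    )
    _write_table(
        root / "activities.csv",
        ["compound_id", "activity_name", "symptoms_addressed",
         "relevant_to_indication", "mechanism", "citations"],
        [
            [c.compound_id, a.activity_name, _join(a.symptoms_addressed),
             a.relevant_to_indication, a.mechanism, _join(a.citations)]
            for c in doc.compounds
            for a in c.activities
        ],
    )
    _write_table(
        root / "standards.csv",
        ["compound_id", "vendor", "grade", "pack_value", "pack_unit", "price_eur"],
        [
            [c.compound_id, s.vendor, s.grade, s.pack_value,
             s.pack_unit.value, s.price_eur]
            for c in doc.compounds
            for s in c.standards
        ],
    )
    _write_table(
        root / "methods.csv",
        ["compound_id", "technique", "matrix", "citation"],
        [
            [c.compound_id, m.technique, m.matrix, m.citation]
            for c in doc.compounds
            for m in c.methods
        ],
    )
    _write_table(
        root / "limits.csv",
        ["compound_id", "authority", "analyte", "limit_ppm", "direction"],
        [
            ["", lim.authority, lim.analyte, lim.limit_ppm, lim.direction]
            for lim in doc.limits
        ]
        + [
            [c.compound_id, lim.authority, lim.analyte, lim.limit_ppm,
             lim.direction]
            for c in doc.compounds
            for lim in c.negative_marker_limits
        ],
    )


def _read_csv_dir(root: Path) -> dict:
    meta = {row["key"]: row["value"] for row in _read_table(root / "meta.csv")}

    indications: dict[str, list[dict]] = {}
    for row in _read_table(root / "indications.csv"):
        indications.setdefault(row["plant"], []).append(
            {"condition": row["condition"], "symptoms": _split(row["symptoms"])}
        )

    plants = [
        {
            "botanical_name": row["botanical_name"],
            "family": row["family"],
            "source": row["source"],
            "part_used": _split(row["part_used"]),
            "dosage_forms": _split(row["dosage_forms"]),
            "indications": indications.get(row["botanical_name"], []),
        }
        for row in _read_table(root / "plants.csv")
    ]

    def group(filename: str) -> dict[str, list[dict]]:
        out: dict[str, list[dict]] = {}
        for row in _read_table(root / filename):
            out.setdefault(row["compound_id"], []).append(row)
        return out

    activities = group("activities.csv")
    standards = group("standards.csv")
    methods = group("methods.csv")
    limit_rows = _read_table(root / "limits.csv")

    compounds = []
    for row in _read_table(root / "compounds.csv"):
        cid = row["compound_id"]
        rc_cells = [row[f"recorded_{k}"] for k in "abcdef"]
        compounds.append(
            {
                "compound_id": cid,
                "name": row["name"],
                "plant": row["plant"],
                "documented_constituent": row["documented_constituent"] == "true",
                "activities": [
                    {
                        "activity_name": a["activity_name"],
                        "symptoms_addressed": _split(a["symptoms_addressed"]),
                        "relevant_to_indication":
                            a["relevant_to_indication"] == "true",
                        "mechanism": a["mechanism"],
                        "citations": _split(a["citations"]),
                    }
                    for a in activities.get(cid, [])
                ],
                "concentration": {
                    "raw_text": row["conc_raw_text"],
                    "determined": row["conc_determined"] == "true",
                    "low": _opt_float(row["conc_low"]),
                    "high": _opt_float(row["conc_high"]),
                    "unit": row["conc_unit"] or None,
                    "basis": row["conc_basis"],
                },
                "standards": [
                    {
                        "vendor": s["vendor"],
                        "grade": s["grade"],
                        "pack_value": float(s["pack_value"]),
                        "pack_unit": s["pack_unit"],
                        "price_eur": float(s["price_eur"]),
                    }
                    for s in standards.get(cid, [])
                ],
                "methods": [
                    {
                        "technique": m["technique"],
                        "matrix": m["matrix"],
                        "citation": m["citation"],
                    }
                    for m in methods.get(cid, [])
                ],
                "toxic": row["toxic"] == "true",
                "negative_marker_limits": [
                    {
                        "authority": lr["authority"],
                        "analyte": lr["analyte"],
                        "limit_ppm": float(lr["limit_ppm"]),
                        "direction": lr["direction"],
                    }
                    for lr in limit_rows
                    if lr["compound_id"] == cid
                ],
                "recorded_components": (
                    None
                    if rc_cells[0] == ""
                    else dict(zip("abcdef", (int(x) for x in rc_cells)))
                ),
                "recorded_total": (
                    None if row["recorded_total"] == ""
                    else int(row["recorded_total"])
                ),
            }
        )

    return {
        "schema_version": meta.get("schema_version", SCHEMA_VERSION),
        "plants": plants,
        "compounds": compounds,
        "limits": [
            {
                "authority": lr["authority"],
                "analyte": lr["analyte"],
                "limit_ppm": float(lr["limit_ppm"]),
                "direction": lr["direction"],
            }
            for lr in limit_rows
            if lr["compound_id"] == ""
        ],
    }


# --------------------------------------------------------------------------
# public readers/writers

def read_dataset(path, format: Optional[str] = None) -> DatasetDocument:
    """Load and validate a dataset in json, yaml, or csv form.

    ``format`` defaults from the path: directories are the CSV dialect,
    ``.yaml``/``.yml`` files YAML, anything else JSON.  Schema problems
    raise :class:`DatasetValidationError` listing every offending field.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "csv"
        elif path.suffix.lower() in (".yaml", ".yml"):
            format = "yaml"
        else:
            format = "json"
    if format == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
    elif format == "yaml":
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    elif format == "csv":
        data = _read_csv_dir(path)
    else:
        raise ValueError(f"unknown dataset format: {format!r}")
    return dataset_from_dict(data)


def write_dataset(doc: DatasetDocument, path, format: Optional[str] = None) -> None:
    """Write a dataset; inverse of :func:`read_dataset` for all formats."""
    path = Path(path)
    if format is None:
        if path.suffix.lower() in (".yaml", ".yml"):
            format = "yaml"
        elif path.suffix.lower() == ".json":
            format = "json"
        else:
            format = "csv"
    data = dataset_to_dict(doc)
    if format == "json":
        path.write_text(
            json.dumps(data, indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
    elif format == "yaml":
        path.write_text(
            yaml.safe_dump(data, allow_unicode=True, sort_keys=False),
            encoding="utf-8",
        )
    elif format == "csv":
        _write_csv_dir(doc, path)
    else:
        raise ValueError(f"unknown dataset format: {format!r}")


# --------------------------------------------------------------------------
# report rendering

_SCORE_HEADER = "A+B+C+D+E+F"


def _fmt_ppm(ppm) -> str:
    if ppm is None:
        return "ND"
    return f"{ppm.value:.2f}".rstrip("0").rstrip(".")


def render_ranking_report(
    tables: list[RankedMarkerTable],
    cost: Optional[CostSummary] = None,
    findings: Optional[AuditReport] = None,
    *,
    dataset: Optional[DatasetDocument] = None,
    header: bool = True,
) -> str:
    """Plain-text ranking report; byte-identical across runs for one input."""
    lines: list[str] = []
    if header:
        lines.append("Herb MaRS marker ranking report")
        lines.append("=" * 31)
        lines.append("")

    cost_index: dict[str, list[float]] = {}
    if dataset is not None:
        for uc in iter_unit_costs(dataset.compounds):
            cost_index.setdefault(uc.compound_id, []).append(uc.rounded)

    col = f"{'compound':<24} A B C D E F  /8 ({_SCORE_HEADER})  suitable  role          ppm        cost €/unit"
    for table in tables:
        lines.append(f"Plant: {table.plant.botanical_name}")
        lines.append(col)
        lines.append("-" * len(col))
        for row in table.rows:
            comp = row.components
            costs = cost_index.get(row.compound_id, [])
            cost_cell = "/".join(f"{c:.1f}" for c in costs) if costs else "-"
            flags = " [screen]" if row.must_screen else ""
            lines.append(
                f"{row.name:<24} {comp.a} {comp.b} {comp.c} {comp.d} {comp.e} {comp.f}  "
                f"{comp.total:>2}{'':<16}{'yes' if row.suitable else 'no ':<9} "
                f"{row.role:<13} {_fmt_ppm(row.ppm):<10} {cost_cell}{flags}"
            )
        lines.append("")

    if cost is not None:
        lines.append(
            "Reference-standard unit costs: "
            f"n={cost.n}, min €{cost.minimum:.1f} ({cost.argmin}), "
            f"max €{cost.maximum:.1f} ({cost.argmax}), "
            f"mean €{cost.mean:.1f} ± {cost.sd:.1f} (sample sd)"
        )
    if findings is not None:
        lines.append(
            "Audit: "
            f"{len(findings.findings)} finding(s) "
            f"[{len(findings.by_kind('sum_mismatch'))} sum, "
            f"{len(findings.by_kind('derivation_mismatch'))} derivation, "
            f"{len(findings.by_kind('availability_mismatch'))} availability], "
            f"{findings.n_audited} audited, {findings.n_skipped} skipped"
        )
        for f in findings.findings:
            lines.append(f"  - {f.detail}")
    return "\n".join(lines) + "\n"
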
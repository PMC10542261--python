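"""Per-plant ranking, marker selection, and scored-table auditing.

Ranking is deterministic: descending total, ties broken by compound name
ascending after Unicode NFKC normalization and casefolding.  Unsuitable
compounds stay in the table (flagged) — a ranking is a report, not a filter;
:func:`select_markers` applies the suitability cut.

The auditor compares a table's *recorded* scores (as printed in a source
document) against the rubric recomputed from the underlying evidence, and
reports — it never repairs.  Three kinds of finding:

* ``sum_mismatch`` — the printed components do not add up to the printed total;
* ``derivation_mismatch`` — a printed evidence component (A–D) differs from
  the value the rubric derives from the recorded evidence;
* ``availability_mismatch`` — a printed availability flag (E or F) contradicts
  the record's own standards/methods listings.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .evidence import CompoundRecord, PlantMaterial
from .scoring import (
    MarkerAssessment,
    SUITABILITY_THRESHOLD,
    score_components,
)

__all__ = [
    "RankedMarkerTable",
    "AuditFinding",
    "AuditReport",
    "rank_compounds",
    "select_markers",
    "audit_dataset",
]


def _sort_key(name: str) -> str:
    return unicodedata.normalize("NFKC", name).casefold()


@dataclass
class RankedMarkerTable:
    """Assessments for one plant, ordered best-first."""

    plant: PlantMaterial
    rows: list[MarkerAssessment] = field(default_factory=list)

    def __iter__(self) -> Iterator[MarkerAssessment]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class AuditFinding:
    """One inconsistency between recorded and recomputed scores."""

    compound_id: str
    kind: str  # "sum_mismatch" | "derivation_mismatch" | "availability_mismatch"
    field: str
    recorded: int
    recomputed: int

    @property
    def detail(self) -> str:
        return (
            f"{self.compound_id}: {self.kind} on {self.field} "
            f"(recorded {self.recorded}, recomputed {self.recomputed})"
        )


@dataclass
class AuditReport:
    """Findings plus the count of rows that carried no recorded scores.

    Iterates as its list of findings, so it can be used anywhere a plain
    findings list is expected.
    """

    findings: list[AuditFinding] = field(default_factory=list)
    n_audited: int = 0
    n_skipped: int = 0

    def __iter__(self) -> Iterator[AuditFinding]:
        return iter(self.findings)

    def __len__(self) -> int:
        return len(self.findings)

    def by_kind(self, kind: str) -> list[AuditFinding]:
        return [f for f in self.findings if f.kind == kind]

    def clean_ids(self, dataset: Iterable[CompoundRecord], kind: Optional[str] = None) -> set[str]:
        """Ids of audited records with no findings (optionally of one kind)."""
        flagged = {
            f.compound_id
            for f in self.findings
            if kind is None or f.kind == kind
        }
        return {
            rec.compound_id
            for rec in dataset
            if (rec.recorded_components is not None or rec.recorded_total is not None)
            and rec.compound_id not in flagged
        }


def rank_compounds(
    plant: PlantMaterial, assessments: Iterable[MarkerAssessment]
) -> RankedMarkerTable:
    """Order assessments by descending total, name-ascending on ties."""
    rows = sorted(
        assessments, key=lambda a: (-a.components.total, _sort_key(a.name))
    )
    return RankedMarkerTable(plant=plant, rows=rows)


def select_markers(
    table: RankedMarkerTable, threshold: int = SUITABILITY_THRESHOLD
) -> list[MarkerAssessment]:
    """Suitable rows scoring at least ``threshold``, in rank order."""
    if not (0 <= threshold <= 9):
        raise ValueError("threshold must be a small non-negative integer")
    return [
        row
        for row in table.rows
        if row.suitable and row.components.total >= threshold
    ]


def audit_dataset(dataset: Iterable[CompoundRecord]) -> AuditReport:
    """Audit every record that carries recorded scores.

    Records with neither ``recorded_components`` nor ``recorded_total`` are
    skipped and counted.  Recorded values stay authoritative in the data;
    the report only describes where they disagree with the rubric.
    """
    report = AuditReport()
    for rec in dataset:
        rc = rec.recorded_components
        rt = rec.recorded_total
        if rc is None and rt is None:
            report.n_skipped += 1
            continue
        report.n_audited += 1

        if rc is not None and rt is not None and rc.total != rt:
            report.findings.append(
                AuditFinding(
                    compound_id=rec.compound_id,
                    kind="sum_mismatch",
                    field="recorded_total",
                    recorded=rt,
                    recomputed=rc.total,
                )
            )

        if rc is not None:
            derived = score_components(rec, validate=False)
            for comp in ("a", "b", "c", "d"):
                if getattr(rc, comp) != getattr(derived, comp):
                    report.findings.append(
                        AuditFinding(
                            compound_id=rec.compound_id,
                            kind="derivation_mismatch",
                            field=comp,
                            recorded=getattr(rc, comp),
                            recomputed=getattr(derived, comp),
                        )
                    )
            for comp in ("e", "f"):
                if getattr(rc, comp) != getattr(derived, comp):
                    report.findings.append(
                        AuditFinding(
                            compound_id=rec.compound_id,
                            kind="availability_mismatch",
                            field=comp,
                            recorded=getattr(rc, comp),
                            recomputed=getattr(derived, comp),
                        )
                    )
    return report
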
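"""Unit costs of analytical reference standards.

Vendors list the smallest commercial pack and its price; roughly 1 mg (or
1 mL) of a standard suffices for one external-calibration series, so the
practical figure is the cost of one denomination unit:

    cost_per_unit = pack price (EUR) / pack value

The denomination is the listing's own pack unit (mg, mL or g) — no
cross-unit conversion is attempted, and summaries pool all denominations
into one column exactly as vendor cost tables do.  A per-denomination
breakdown is exposed alongside as a corrective view.

Costs are conventionally printed to one decimal (half-up); summary
statistics are computed over the rounded values by default so that they
agree with a printed cost column, with the unrounded variant available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from statistics import mean, stdev
from typing import Iterable, Optional

from .evidence import CompoundRecord, StandardListing

__all__ = ["UnitCost", "CostSummary", "unit_cost", "cost_summary", "round_half_up_1dp"]


def round_half_up_1dp(x: float) -> float:
    """Round to 1 decimal place with ties away from zero (2.45 → 2.5)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class UnitCost:
    """EUR per single pack-denomination unit of one listing."""

    compound_id: str
    listing: StandardListing
    cost_per_unit: float
    rounded: float


@dataclass
class CostSummary:
    """Dataset-wide summary over per-listing unit costs (one value per
    priced listing, pooled across denominations)."""

    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float  # sample (n-1); 0.0 when n == 1
    argmin: str
    argmax: str
    rounded_inputs: bool = True
    by_denomination: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "minimum": self.minimum,
            "maximum": self.maximum,
            "mean": self.mean,
            "sd": self.sd,
            "argmin": self.argmin,
            "argmax": self.argmax,
            "rounded_inputs": self.rounded_inputs,
            "by_denomination": self.by_denomination,
        }


def unit_cost(compound_id: str, listing: StandardListing) -> UnitCost:
    """Cost of one mg/mL/g of the standard, from the listing's own pack."""
    if listing.pack_value is None or listing.pack_value <= 0:
        raise ValueError(
            f"{compound_id}: pack_value must be positive, got {listing.pack_value!r}"
        )
    if listing.price_eur is None or listing.price_eur <= 0:
        raise ValueError(
            f"{compound_id}: price_eur must be positive, got {listing.price_eur!r}"
        )
    cost = listing.price_eur / listing.pack_value
    return UnitCost(
        compound_id=compound_id,
        listing=listing,
        cost_per_unit=cost,
        rounded=round_half_up_1dp(cost),
    )


def iter_unit_costs(dataset: Iterable[CompoundRecord]) -> list[UnitCost]:
    """All per-listing unit costs in the dataset, in record order."""
    return [
        unit_cost(rec.compound_id, listing)
        for rec in dataset
        for listing in rec.standards
    ]


def cost_summary(
    dataset: Iterable[CompoundRecord], *, rounded: bool = True
) -> CostSummary:
    """Min/max/mean/sd over every priced listing's unit cost.

    One value per listing (a compound with three listings contributes three
    values).  ``rounded=True`` (default) summarizes the 1-dp rounded costs,
    matching a printed cost column; ``rounded=False`` uses exact quotients.
    """
    costs = iter_unit_costs(dataset)
    if not costs:
        raise ValueError("no priced standard listings in the dataset")

    def val(uc: UnitCost) -> float:
        return uc.rounded if rounded else uc.cost_per_unit

    values = [val(uc) for uc in costs]
    lo = min(costs, key=val)
    hi = max(costs, key=val)

    by_denom: dict[str, dict[str, float]] = {}
    for unit_name in sorted({uc.listing.pack_unit.value for uc in costs}):
        sub = [val(uc) for uc in costs if uc.listing.pack_unit.value == unit_name]
        by_denom[unit_name] = {
            "n": len(sub),
            "minimum": min(sub),
            "maximum": max(sub),
            "mean": mean(sub),
            "sd": stdev(sub) if len(sub) > 1 else 0.0,
        }

    return CostSummary(
        n=len(values),
        minimum=val(lo),
        maximum=val(hi),
        mean=mean(values),
        sd=stdev(values) if len(values) > 1 else 0.0,
        argmin=lo.compound_id,
        argmax=hi.compound_id,
        rounded_inputs=rounded,
        by_denomination=by_denom,
    )
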
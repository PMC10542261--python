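"""Parsing and ppm-normalization of literature concentration reports.

Concentration evidence in the source tables is free text — "0.50% of
essential oil", "0.018 to 0.64 mg/g of oil", "109-135ppm of gel", "ND".
The rubric's thresholds (5 ppm and 50 ppm) are mass fractions, so every
report is normalized to parts per million (w/w):

    1 % w/w  = 10,000 ppm        1 mg/g = 1,000 ppm

Ranges collapse to their arithmetic midpoint (the only parameter-free
"mean" given a low and a high).  The matrix ("basis": oil, gel, stem bark,
...) is carried along as metadata but never rescales the value — a
percentage *of essential oil* is scored as such.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .evidence import ConcentrationReport, Unit

__all__ = [
    "PpmValue",
    "UNDETERMINED",
    "ConcentrationParseError",
    "parse_concentration",
    "format_concentration",
    "to_ppm",
    "PPM_PER_UNIT",
]

#: Mass-fraction conversion factors to ppm, by reporting unit.
PPM_PER_UNIT: dict[Unit, float] = {
    Unit.PERCENT_W_W: 10_000.0,
    Unit.MG_PER_G: 1_000.0,
    Unit.PPM: 1.0,
}

#: Sentinel for reports whose concentration was never measured ("ND").
UNDETERMINED = None


@dataclass(frozen=True)
class PpmValue:
    """A normalized concentration in ppm (mass basis)."""

    value: float
    provenance: str  # "point" | "range_midpoint"
    basis: str = ""


class ConcentrationParseError(ValueError):
    """Raised when a concentration string matches no known dialect."""


_ND_RE = re.compile(r"^\s*(nd|not\s+determined)\s*$", re.IGNORECASE)

# "<low>[ –|-|—|to <high>] <unit>[ of <basis>]"; en dash, em dash, hyphen and
# the word "to" all separate ranges; "ppm" may abut the number (109-135ppm).
_NUMBER = r"\d+(?:\.\d+)?"
_CONC_RE = re.compile(
    rf"^\s*(?P<low>{_NUMBER})\s*"
    rf"(?:(?:–|—|-|\bto\b)\s*(?P<high>{_NUMBER})\s*)?"
    rf"(?P<unit>%|mg/g|ppm)"
    rf"(?:\s+of\s+(?P<basis>.+?))?\s*$"
)

_UNIT_TOKENS = {"%": Unit.PERCENT_W_W, "mg/g": Unit.MG_PER_G, "ppm": Unit.PPM}
_UNIT_SUFFIX = {Unit.PERCENT_W_W: "%", Unit.MG_PER_G: " mg/g", Unit.PPM: " ppm"}


def parse_concentration(raw: str) -> ConcentrationReport:
    """Parse one free-text concentration report.

    Recognized dialects: "ND"/"Not determined"; single values and ranges in
    % w/w, mg/g, or ppm, with an optional "of <matrix>" suffix.  Anything
    else raises :class:`ConcentrationParseError` naming the offending text —
    unparseable input is never silently coerced to not-determined.
    """
    if not raw or not raw.strip():
        raise ConcentrationParseError("empty concentration text")
    if _ND_RE.match(raw):
        return ConcentrationReport(raw_text=raw, determined=False)
    m = _CONC_RE.match(raw)
    if m is None:
        raise ConcentrationParseError(
            f"unrecognized concentration pattern: {raw!r}"
        )
    low = float(m.group("low"))
    high = float(m.group("high")) if m.group("high") else low
    return ConcentrationReport(
        raw_text=raw,
        determined=True,
        low=low,
        high=high,
        unit=_UNIT_TOKENS[m.group("unit")],
        basis=m.group("basis") or "",
    )


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def format_concentration(report: ConcentrationReport) -> str:
    """Render a report as text; the verbatim source string wins if present."""
    if report.raw_text:
        return report.raw_text
    if not report.determined:
        return "ND"
    if report.low == report.high:
        body = _fmt_num(report.low)
    else:
        body = f"{_fmt_num(report.low)}–{_fmt_num(report.high)}"
    body += _UNIT_SUFFIX[report.unit]
    if report.basis:
        body += f" of {report.basis}"
    return body


def to_ppm(report: ConcentrationReport):
    """Normalize a report to a scalar ppm value.

    Returns :data:`UNDETERMINED` for not-determined reports; otherwise a
    :class:`PpmValue` whose value is the converted point value, or the
    arithmetic midpoint of the converted bounds for a range
    (``provenance="range_midpoint"``).
    """
    if not report.determined:
        return UNDETERMINED
    factor = PPM_PER_UNIT[report.unit]
    low = report.low * factor
    high = report.high * factor
    if low == high:
        return PpmValue(value=low, provenance="point", basis=report.basis)
    return PpmValue(
        value=(low + high) / 2.0, provenance="range_midpoint", basis=report.basis
    )
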
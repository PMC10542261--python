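"""Concentration parsing and ppm normalization."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbmars import (
    ConcentrationParseError,
    ConcentrationReport,
    Unit,
    format_concentration,
    parse_concentration,
    to_ppm,
)
from herbmars.units import UNDETERMINED


@pytest.mark.parametrize("raw,low,high,unit,basis", [
    ("0.50% of essential oil", 0.50, 0.50, Unit.PERCENT_W_W, "essential oil"),
    ("10–30% of essential oil", 10.0, 30.0, Unit.PERCENT_W_W, "essential oil"),
    ("0.018 to 0.64 mg/g of oil", 0.018, 0.64, Unit.MG_PER_G, "oil"),
    ("109-135ppm of gel", 109.0, 135.0, Unit.PPM, "gel"),
    ("19–200 ppm of stem bark", 19.0, 200.0, Unit.PPM, "stem bark"),
    ("1.1-2.0 mg/g of rhizome", 1.1, 2.0, Unit.MG_PER_G, "rhizome"),
    ("97.32%", 97.32, 97.32, Unit.PERCENT_W_W, ""),
])
def test_parse_recognized_dialects(raw, low, high, unit, basis):
    rep = parse_concentration(raw)
    assert rep.determined
    assert (rep.low, rep.high, rep.unit, rep.basis) == (low, high, unit, basis)
    assert rep.raw_text == raw


@pytest.mark.parametrize("raw", ["ND", "Not determined", "  nd  "])
def test_parse_not_determined(raw):
    rep = parse_concentration(raw)
    assert not rep.determined
    assert rep.low is None and rep.unit is None


@pytest.mark.parametrize("raw", ["", "trace amounts", "5 µg/mL", "10-20"])
def test_unrecognized_text_raises_never_silently_nd(raw):
    with pytest.raises(ConcentrationParseError):
        parse_concentration(raw)


@pytest.mark.parametrize("raw,ppm,provenance", [
    ("0.50% of essential oil", 5000.0, "point"),
    ("1.1-2.0 mg/g of rhizome", 1550.0, "range_midpoint"),
    ("109-135ppm of gel", 122.0, "range_midpoint"),
    ("8.07 mg/g of stem bark", 8070.0, "point"),
])
def test_to_ppm_conversions(raw, ppm, provenance):
    val = to_ppm(parse_concentration(raw))
    assert val.value == pytest.approx(ppm)
    assert val.provenance == provenance


def test_not_determined_maps_to_sentinel():
    assert to_ppm(parse_concentration("ND")) is UNDETERMINED


def test_fixture_concentrations_roundtrip_through_parser(reference):
    """parse ∘ format is the identity on every packaged concentration."""
    for rec in reference.compounds:
        rep = rec.concentration
        again = parse_concentration(format_concentration(rep))
        assert again == rep, rec.compound_id


@given(
    value=st.floats(min_value=1e-6, max_value=1e6,
                    allow_nan=False, allow_infinity=False),
)
def test_percent_equals_ten_times_mg_per_g(value):
    pct = ConcentrationReport("", True, value, value, Unit.PERCENT_W_W)
    mgg = ConcentrationReport("", True, 10 * value, 10 * value, Unit.MG_PER_G)
    assert to_ppm(pct).value == pytest.approx(to_ppm(mgg).value)


@given(
    low=st.floats(min_value=0, max_value=1e5, allow_nan=False),
    width=st.floats(min_value=0, max_value=1e5, allow_nan=False),
    unit=st.sampled_from(list(Unit)),
)
def test_ppm_identity_and_midpoint_bounds(low, width, unit):
    rep = ConcentrationReport("", True, low, low + width, unit)
    val = to_ppm(rep)
    if unit is Unit.PPM and width == 0:
        assert val.value == low  # ppm -> ppm is the identity
    lo, hi = sorted((to_ppm(ConcentrationReport("", True, x, x, unit)).value
                     for x in (low, low + width)))
    assert lo <= val.value <= hi


@given(
    mid1=st.floats(min_value=0, max_value=1e6, allow_nan=False),
    mid2=st.floats(min_value=0, max_value=1e6, allow_nan=False),
)
def test_conversion_monotone_in_concentration_points(mid1, mid2):
    """Higher converted midpoints never earn fewer concentration points."""
    def points(ppm):
        return (1 if ppm >= 5 else 0) + (1 if ppm >= 50 else 0)

    v1 = to_ppm(ConcentrationReport("", True, mid1, mid1, Unit.PPM)).value
    v2 = to_ppm(ConcentrationReport("", True, mid2, mid2, Unit.PPM)).value
    if v1 <= v2:
        assert points(v1) <= points(v2)
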
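"""Cytogenetic parsing, ordering, and candidate-region narrowing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndjscreen import CytoBand, band_le, candidate_region, parse_band, parse_interval
from ndjscreen.errors import (
    CytoParseError,
    NoConsistentRegionError,
    UnsupportedRearrangementError,
)


def test_precise_breakpoints_parse():
    interval = parse_interval("77A1;77D1")
    assert interval.proximal.precise and interval.distal.precise
    assert str(interval.proximal.earliest) == "77A1"
    assert str(interval.distal.latest) == "77D1"


def test_uncertain_breakpoints_parse_to_ranges():
    interval = parse_interval("66B12-C1;66D2-4")
    assert (str(interval.proximal.earliest), str(interval.proximal.latest)) == ("66B12", "66C1")
    assert (str(interval.distal.earliest), str(interval.distal.latest)) == ("66D2", "66D4")


def test_bare_subdivision_spans_whole_subdivision():
    interval = parse_interval("97F1-2;98A")
    distal = interval.distal.earliest
    assert distal.band is None
    assert str(distal.earliest()) == "98A1"


def test_degenerate_single_band_interval():
    interval = parse_interval("77B2;77B2")
    assert interval.proximal == interval.distal


def test_complex_rearrangement_is_flagged_not_fatal():
    with pytest.raises(UnsupportedRearrangementError):
        parse_interval("83D4-5;84A4-5;98F1-2")
    with pytest.raises(UnsupportedRearrangementError):
        parse_interval("83C1-2;84B1-2, 83D4-5;84A4-5;98F1-2")


@pytest.mark.parametrize("text", ["", "77", "77G2;78A1", "77A1", "5A1;6B2", "77A1;x"])
def test_malformed_text_raises_parse_error(text):
    with pytest.raises(CytoParseError):
        parse_interval(text)


@pytest.mark.parametrize(
    "a, b",
    [("66B12", "66C1"), ("77B2", "77B3"), ("80F", "81A"), ("61A1", "100F")],
)
def test_band_ordering(a, b):
    assert band_le(parse_band(a), parse_band(b))
    assert not band_le(parse_band(b), parse_band(a))


def test_roundtrip_rendering_is_idempotent_on_every_bundled_string(
    deficiency_rows, polo_rows, region_table
):
    strings = [r.breakpoints for r in deficiency_rows + polo_rows if r.breakpoints]
    strings += region_table["breakpoints"].tolist()
    extra = [  # overlap-test deficiencies quoted in the narrowing arguments
        "97D2;97F1", "97E1;97E5", "97E4;97E11", "97F1-2;98A", "97E2;98A7",
        "86D8;86E13", "86E13;86E18", "86E18;87A1", "86F9;87B13",
        "73B5;73E5", "73A2;73C1", "73D1;73D5", "73D5;73E4", "73E1;74C3",
        "69D4-5;69F5-7", "69B1-5;69D1-6", "69D1;69E2", "69D2;69E3-5", "69C4;69F6",
        "94E1-2;94F1-2", "94D3;94E4", "94D3;94E9", "94E4;94E11", "94F1;95A4",
    ]
    for text in dict.fromkeys(strings + extra):
        assert str(parse_interval(text)) == text


@pytest.mark.parametrize(
    "positives, negatives, expected",
    [
        # the three published narrowing arguments
        (["77A1;77D1", "76D3;77C1", "77B2;77C6"], [], "77B2;77C1"),
        (
            ["94E1-2;94F1-2", "94E4;94E11"],
            ["94D2-10;94E1-6", "94D3;94E4", "94D3;94E9", "94F1;95A4"],
            "94E9;94E11",
        ),
        (
            ["97E2;98A3-4", "97E2;98A7"],
            ["97D2;97F1", "97E1;97E5", "97E4;97E11", "97F1-2;98A"],
            "98A1;98A4",
        ),
    ],
)
def test_candidate_region_reproduces_published_regions(positives, negatives, expected):
    assert str(candidate_region(positives, negatives)) == expected


def test_candidate_region_commutative_and_shrinking():
    positives = ["97E2;98A3-4", "97E2;98A7"]
    negatives = ["97D2;97F1", "97E1;97E5", "97E4;97E11", "97F1-2;98A"]
    base = str(candidate_region(positives, negatives))
    assert str(candidate_region(positives[::-1], negatives[::-1])) == base
    # adding a negative can never enlarge the reported region
    import itertools

    def span(result):
        from ndjscreen.cytomap import _ordinal

        return _ordinal(result.possible_hi.key_high()) - _ordinal(result.possible_lo.key_low())

    full = span(candidate_region(positives, negatives))
    for subset_size in range(len(negatives)):
        for subset in itertools.combinations(negatives, subset_size):
            assert span(candidate_region(positives, list(subset))) >= full


def test_singleton_positive_returns_its_own_interval():
    assert str(candidate_region(["77A1;77D1"])) == "77A1;77D1"


def test_disjoint_positives_raise():
    with pytest.raises(NoConsistentRegionError):
        candidate_region(["61A1;62B1", "99A1;100C1"])


def test_negatives_covering_everything_raise():
    with pytest.raises(NoConsistentRegionError):
        candidate_region(["77B1;77C5"], ["77A1;77D1"])


def test_empty_positive_set_raises():
    with pytest.raises(NoConsistentRegionError):
        candidate_region([])


divisions = st.integers(61, 100)
subdivisions = st.sampled_from("ABCDEF")
bands = st.integers(1, 17)


@given(
    d1=divisions, s1=subdivisions, b1=bands, d2=divisions, s2=subdivisions, b2=bands
)
@settings(max_examples=100, derandomize=True)
def test_band_order_is_total_and_antisymmetric(d1, s1, b1, d2, s2, b2):
    a, b = CytoBand(d1, s1, b1), CytoBand(d2, s2, b2)
    assert band_le(a, b) or band_le(b, a)
    if band_le(a, b) and band_le(b, a):
        assert a == b
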
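"""Cytogenetic-band calculus for deficiency breakpoints on chromosome 3.

Deficiency breakpoints are reported on the polytene map as
division (61-100), subdivision (A-F) and band number, e.g. ``77B2``, often
with uncertainty ranges (``66B12-C1`` means "somewhere between 66B12 and
66C1") or missing precision (bare ``98A`` spans the whole subdivision). The
calculus here is purely cytological — many stocks lack molecular
breakpoints — and supports the screen's region-narrowing argument:

* a deficiency that modifies the phenotype (a *positive*) localizes the
  gene inside its **possible** deleted region (widest reading of the
  breakpoint uncertainty);
* a deficiency that does not (a *negative*) excludes only its **certainly**
  deleted region: the bands strictly between its proximal and distal
  breakpoints. Breakpoint bands themselves may be only partially deleted,
  so they are conservatively retained.

Subtraction can therefore leave several disjoint fragments, e.g. the
retained breakpoint bands of a negative next to the true candidate region;
:func:`candidate_region` returns the largest fragment (most distal on
ties), which is the reading under which the retained slivers do not
displace the interval the overlap logic actually pins down.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterable, Sequence

from .errors import CytoParseError, NoConsistentRegionError, UnsupportedRearrangementError

_SUBDIVISIONS = "ABCDEF"
#: Open upper sentinel for bands per subdivision (never enumerated on the
#: map itself; only used to order whole-subdivision spans and size fragments).
_BAND_CAP = 30

_BAND_RE = re.compile(r"^(\d{2,3})([A-F])?(\d{1,2})?$")


@total_ordering
@dataclass(frozen=True)
class CytoBand:
    """One position on the polytene map of chromosome 3.

    ``subdivision`` and ``band`` may be missing; a band number requires a
    subdivision. A missing component denotes the whole enclosing span.
    """

    division: int
    subdivision: str | None = None
    band: int | None = None

    def __post_init__(self) -> None:
        if not 61 <= self.division <= 100:
            raise CytoParseError(
                f"division {self.division} outside chromosome 3 numbering 61-100"
            )
        if self.subdivision is not None and self.subdivision not in _SUBDIVISIONS:
            raise CytoParseError(f"subdivision {self.subdivision!r} not in A-F")
        if self.band is not None:
            if self.subdivision is None:
                raise CytoParseError(f"band number without subdivision in {self!r}")
            if not 1 <= self.band <= _BAND_CAP:
                raise CytoParseError(f"band number {self.band} outside 1-{_BAND_CAP}")

    # -- ordering (spans compare by earliest position; see key_high for
    #    upper-bound contexts) ------------------------------------------
    def key_low(self) -> tuple[int, int, int]:
        sub = _SUBDIVISIONS.index(self.subdivision) if self.subdivision else 0
        return (self.division, sub, self.band or 1)

    def key_high(self) -> tuple[int, int, int]:
        sub = _SUBDIVISIONS.index(self.subdivision) if self.subdivision else 5
        return (self.division, sub, self.band or _BAND_CAP)

    def __lt__(self, other: "CytoBand") -> bool:
        return self.key_low() < other.key_low()

    def earliest(self) -> "CytoBand":
        """The first concrete band inside this (possibly partial) span."""
        return CytoBand(self.division, self.subdivision or "A", self.band or 1)

    def __str__(self) -> str:
        return f"{self.division}{self.subdivision or ''}{self.band or ''}"


def band_le(a: CytoBand, b: CytoBand) -> bool:
    """Total order on map positions; spans compare by earliest position."""
    return a.key_low() <= b.key_low()


def _ordinal(key: tuple[int, int, int]) -> int:
    division, sub, band = key
    return ((division - 61) * len(_SUBDIVISIONS) + sub) * _BAND_CAP + band


def parse_band(text: str) -> CytoBand:
    m = _BAND_RE.match(text)
    if not m:
        raise CytoParseError("unrecognized band", text=text, position=0)
    division, sub, band = m.groups()
    return CytoBand(int(division), sub, int(band) if band else None)


def _parse_band_relative(text: str, context: CytoBand, position: int) -> CytoBand:
    """Parse the second half of a range, inheriting omitted components."""
    if text.isdigit() and int(text) < 61 and context.subdivision is not None:
        # bare band number, e.g. "4" in "66D2-4" (divisions start at 61)
        return CytoBand(context.division, context.subdivision, int(text))
    if _BAND_RE.match(text):
        return parse_band(text)
    m = re.match(r"^([A-F])(\d{1,2})?$", text)
    if m:  # e.g. "C1" in "66B12-C1"
        sub, band = m.groups()
        return CytoBand(context.division, sub, int(band) if band else None)
    raise CytoParseError("unrecognized range component", text=text, position=position)


@dataclass(frozen=True)
class BreakpointRange:
    """Uncertainty range of a single breakpoint; precise when earliest==latest."""

    earliest: CytoBand
    latest: CytoBand

    def __post_init__(self) -> None:
        if self.earliest.key_low() > self.latest.key_high():
            raise CytoParseError(
                f"breakpoint range out of order: {self.earliest} > {self.latest}"
            )

    @property
    def precise(self) -> bool:
        return self.earliest == self.latest

    def __str__(self) -> str:
        if self.precise:
            return str(self.earliest)
        a, b = self.earliest, self.latest
        if a.division == b.division and a.subdivision == b.subdivision:
            return f"{a}-{b.band}"
        if a.division == b.division:
            return f"{a}-{b.subdivision}{b.band or ''}"
        return f"{a}-{b}"


def parse_breakpoint_range(text: str, position: int = 0) -> BreakpointRange:
    parts = text.split("-")
    if len(parts) == 1:
        band = parse_band(text)
        return BreakpointRange(band, band)
    if len(parts) == 2:
        first = parse_band(parts[0])
        second = _parse_band_relative(parts[1], first, position + len(parts[0]) + 1)
        return BreakpointRange(first, second)
    raise CytoParseError("too many '-' in breakpoint range", text=text, position=position)


@dataclass(frozen=True)
class CytoInterval:
    """A deficiency's deleted region, bounded by two uncertain breakpoints."""

    proximal: BreakpointRange
    distal: BreakpointRange

    def __post_init__(self) -> None:
        if self.proximal.earliest.key_low() > self.distal.latest.key_high():
            raise CytoParseError(
                f"interval out of order: {self.proximal} > {self.distal}"
            )

    @property
    def possible_lo(self) -> CytoBand:
        """Proximal edge of the widest possibly-deleted span."""
        return self.proximal.earliest

    @property
    def possible_hi(self) -> CytoBand:
        return self.distal.latest

    def __str__(self) -> str:
        return f"{self.proximal};{self.distal}"


def parse_interval(text: str) -> CytoInterval:
    """Parse a two-breakpoint deficiency string like ``"66B12-C1;66D2-4"``.

    Raises
    ------
    UnsupportedRearrangementError
        For strings with more than two breakpoints (complex rearrangements).
    CytoParseError
        For malformed text; the error carries the failing position.
    """
    cleaned = text.strip()
    if not cleaned:
        raise CytoParseError("empty breakpoint string", text=text, position=0)
    if "," in cleaned or cleaned.count(";") > 1:
        raise UnsupportedRearrangementError(
            "more than two breakpoints (complex rearrangement)", text=text, position=0
        )
    if ";" not in cleaned:
        raise CytoParseError("expected 'proximal;distal'", text=text, position=len(cleaned))
    left, right = cleaned.split(";")
    proximal = parse_breakpoint_range(left.strip(), position=0)
    distal = parse_breakpoint_range(right.strip(), position=len(left) + 1)
    return CytoInterval(proximal, distal)


# ---------------------------------------------------------------------------
# region arithmetic


@dataclass(frozen=True)
class _Segment:
    """Closed run of bands [lo, hi] (endpoints may be whole-subdivision spans)."""

    lo: CytoBand
    hi: CytoBand

    def span(self) -> int:
        return _ordinal(self.hi.key_high()) - _ordinal(self.lo.key_low())


def _subtract_certain(segment: _Segment, negative: CytoInterval) -> list[_Segment]:
    """Remove a negative's certainly-deleted bands from one segment.

    The certain region is the *open* span strictly between the negative's
    latest proximal and earliest distal breakpoint bands — the breakpoint
    bands themselves are retained as possibly partially deleted.
    """
    a = negative.proximal.latest  # kept; deletion certain only beyond it
    b = negative.distal.earliest  # kept; deletion certain only before it
    zone_lo, zone_hi = a.key_high(), b.key_low()
    if zone_lo >= zone_hi:
        return [segment]  # degenerate deficiency: nothing certainly deleted
    s_lo, s_hi = segment.lo.key_low(), segment.hi.key_high()
    if zone_lo >= s_hi or zone_hi <= s_lo:
        return [segment]
    pieces: list[_Segment] = []
    if zone_lo >= s_lo:  # left remainder up to and including band a
        left_hi = a if a.key_high() < s_hi else segment.hi
        if segment.lo.key_low() <= left_hi.key_high():
            pieces.append(_Segment(segment.lo, left_hi))
    if zone_hi <= s_hi:  # right remainder from band b on
        right_lo = b.earliest() if b.key_low() > s_lo else segment.lo
        if right_lo.key_low() <= segment.hi.key_high():
            pieces.append(_Segment(right_lo, segment.hi))
    return pieces


def candidate_region(
    positives: Iterable[CytoInterval | str],
    negatives: Iterable[CytoInterval | str] = (),
) -> CytoInterval:
    """Narrow a candidate region from modifier-positive and -negative deficiencies.

    Intersects the positives' possible regions, then subtracts each
    negative's certainly-deleted bands. If the subtraction fragments the
    region, the largest fragment is returned (most distal on ties); see the
    module docstring for why retained breakpoint slivers are set aside.

    Inputs may be parsed :class:`CytoInterval` objects or breakpoint strings.

    Raises
    ------
    NoConsistentRegionError
        If no band survives — the screen calls are mutually inconsistent.
    """
    pos: Sequence[CytoInterval] = [
        p if isinstance(p, CytoInterval) else parse_interval(p) for p in positives
    ]
    neg: Sequence[CytoInterval] = [
        n if isinstance(n, CytoInterval) else parse_interval(n) for n in negatives
    ]
    if not pos:
        raise NoConsistentRegionError("at least one positive deficiency is required")

    lo = max((p.possible_lo for p in pos), key=CytoBand.key_low)
    hi = min((p.possible_hi for p in pos), key=CytoBand.key_high)
    if lo.key_low() > hi.key_high():
        raise NoConsistentRegionError(
            "positive deficiencies share no possibly-deleted band"
        )
    segments = [_Segment(lo, hi)]
    for n in neg:
        segments = [piece for seg in segments for piece in _subtract_certain(seg, n)]
        if not segments:
            raise NoConsistentRegionError(
                "negative deficiencies eliminate every candidate band"
            )
    best = max(segments, key=lambda s: (s.span(), s.lo.key_low()))
    return CytoInterval(
        BreakpointRange(best.lo, best.lo), BreakpointRange(best.hi, best.hi)
    )
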
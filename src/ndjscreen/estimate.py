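"""Viability-corrected nondisjunction estimator and control summaries.

Only half of the exceptional zygotes survive (triplo-X and nullo-X die), so
each surviving exceptional fly stands for two nondisjunctional meioses:

    adjusted total = normal + 2 * (exceptional females + exceptional males)
    X NDJ          = 2 * (exceptional females + exceptional males) / adjusted total

Frequencies are stored as fractions; every printed value is a percentage
rendering rounded half-up to two decimals, and the screening band is formed
from those two-decimal summaries (see :func:`control_summary`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .errors import InsufficientDataError, ParameterError, UndefinedEstimateError


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    if not math.isfinite(value):
        return value
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def as_percent(fraction: float, ndigits: int = 2) -> float:
    """Render a frequency fraction as a percentage rounded half-up."""
    return round_half_up(100.0 * fraction, ndigits)


def format_percent(fraction: float, ndigits: int = 2) -> str:
    return f"{as_percent(fraction, ndigits):.{ndigits}f}%"


@dataclass(frozen=True)
class ProgenyCounts:
    """Counts of the three scoreable progeny classes of one cross.

    ``normal`` pools regular females (X/C(1;Y)) and regular males (X/O);
    ``exc_female`` are XX/O exceptional females; ``exc_male`` are O/C(1;Y)
    exceptional males.
    """

    normal: int
    exc_female: int
    exc_male: int

    def __post_init__(self) -> None:
        for name in ("normal", "exc_female", "exc_male"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ParameterError(f"{name}={value!r} is not an integer count")
            if value < 0:
                raise ParameterError(f"{name}={value!r} is negative")

    @property
    def exceptional(self) -> int:
        return self.exc_female + self.exc_male

    @property
    def survivors(self) -> int:
        """Observed survivor total (the binomial sample size of the test)."""
        return self.normal + self.exceptional


@dataclass(frozen=True)
class NDJEstimate:
    """Viability-corrected NDJ frequency with its adjusted denominator."""

    adjusted_total: int
    ndj: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndj <= 1.0:
            raise ParameterError(f"ndj={self.ndj!r} outside [0, 1]")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ParameterError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not 0.0 <= self.ci_low <= self.ndj <= self.ci_high <= 1.0:
                raise ParameterError("confidence bounds must satisfy 0 <= lo <= ndj <= hi <= 1")

    @property
    def percent(self) -> float:
        """Display value: percentage rounded half-up to two decimals."""
        return as_percent(self.ndj)


def adjusted_total(counts: ProgenyCounts) -> int:
    """Progeny total with each surviving exceptional fly counted twice."""
    return counts.normal + 2 * counts.exceptional


def ndj_frequency(counts: ProgenyCounts) -> NDJEstimate:
    """Viability-corrected X NDJ frequency.

    Raises
    ------
    UndefinedEstimateError
        If the adjusted total is zero (no progeny at all).
    """
    total = adjusted_total(counts)
    if total == 0:
        raise UndefinedEstimateError("NDJ frequency undefined for zero adjusted total")
    return NDJEstimate(adjusted_total=total, ndj=2 * counts.exceptional / total)


@dataclass(frozen=True)
class ControlSummary:
    """Control mean, sample SD, and the screening band mean +/- k*SD.

    ``mean`` and ``sd`` are unrounded fractions. The band edges are defined
    on the two-decimal percent scale — the operational thresholds of a
    screen are the printed summaries, and rounding mean and SD before
    adding them is not the same as rounding their sum. ``band_multiplier``
    widens or narrows the band (default one SD).
    """

    mean: float
    sd: float
    band_low: float
    band_high: float
    n: int
    band_multiplier: float = 1.0


def control_summary(
    frequencies: Iterable[float], band_multiplier: float = 1.0
) -> ControlSummary:
    """Summarize control NDJ frequencies (fractions) across rounds.

    Uses the sample standard deviation (n-1 denominator). Requires at least
    two values.
    """
    values: Sequence[float] = list(frequencies)
    if len(values) < 2:
        raise InsufficientDataError(
            f"control summary needs at least 2 frequencies, got {len(values)}"
        )
    if band_multiplier < 0:
        raise ParameterError(f"band_multiplier={band_multiplier!r} is negative")
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    mean_pct, sd_pct = as_percent(mean), as_percent(sd)
    return ControlSummary(
        mean=mean,
        sd=sd,
        band_low=(mean_pct - band_multiplier * sd_pct) / 100.0,
        band_high=(mean_pct + band_multiplier * sd_pct) / 100.0,
        n=n,
        band_multiplier=band_multiplier,
    )


def delta(deficiency_ndj: float, reference_ndj: float) -> float:
    """Signed difference between two NDJ frequencies (same scale in and out).

    Pass fractions to get a fraction, or printed percentages to get the
    difference in percentage points exactly as tables report it.
    """
    return deficiency_ndj - reference_ndj
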
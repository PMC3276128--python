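"""Two-criterion enhancer/suppressor calls and the screen-level report.

A deficiency is called a modifier only if it clears *both* hurdles:

1. its NDJ frequency lies outside the control band (mean +/- one sample SD
   of the per-round control frequencies, exclusive edges), and
2. it differs significantly from its own round's matched control under the
   multinomial-Poisson hierarchy test, in the same direction.

Sterility and lethality are phenotypic observations carried by the input's
status flag; they are never inferred from counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import cytomap
from .errors import ConfigurationError
from .estimate import (
    ControlSummary,
    ProgenyCounts,
    as_percent,
    control_summary,
    ndj_frequency,
    round_half_up,
)
from .hierarchy import TestResult, compare_to_control
from .io import CountTableRow

logger = logging.getLogger(__name__)

Category = Literal["enhancer", "suppressor", "no_effect", "sterile", "lethal", "untested"]
CATEGORIES: tuple[Category, ...] = (
    "enhancer",
    "suppressor",
    "no_effect",
    "sterile",
    "lethal",
    "untested",
)


@dataclass(frozen=True)
class ScreenCall:
    """Classification of one genotype against the control band and its control.

    ``delta_matched`` is the unrounded frequency difference to the matched
    control; ``delta_average`` is computed on the two-decimal percent scale
    (printed frequency minus printed control mean) because that is the scale
    screen tables report — see the methods note.
    """

    genotype: str
    category: Category
    ndj: float | None = None
    delta_matched: float | None = None
    delta_average: float | None = None
    p_value: float | None = None
    test: TestResult | None = None
    breakpoints: str = ""


def classify(
    genotype: str,
    counts: ProgenyCounts | None,
    matched_control: ProgenyCounts | None,
    band: ControlSummary,
    alpha: float = 0.05,
    status: str = "ok",
    breakpoints: str = "",
    p_value: float | None = None,
) -> ScreenCall:
    """Classify one genotype.

    ``status`` of ``sterile``/``lethal``/``untested`` short-circuits to that
    category. Otherwise both counts and the matched control are required.
    ``p_value`` overrides the matched-control test's p-value (used for
    multiplicity-adjusted calls); the direction still comes from the test.
    """
    if status in ("sterile", "lethal", "untested"):
        return ScreenCall(genotype=genotype, category=status, breakpoints=breakpoints)
    if counts is None:
        raise ConfigurationError(f"genotype {genotype!r}: status 'ok' but no counts")
    if matched_control is None:
        raise ConfigurationError(f"genotype {genotype!r} has counts but no matched control")
    estimate = ndj_frequency(counts)
    result = compare_to_control(counts, matched_control, alpha=alpha)
    p = result.p_value if p_value is None else p_value
    delta_matched = estimate.ndj - ndj_frequency(matched_control).ndj
    delta_average = (as_percent(estimate.ndj) - as_percent(band.mean)) / 100.0
    category: Category = "no_effect"
    if estimate.ndj > band.band_high and p < alpha and result.direction == "higher":
        category = "enhancer"
    elif estimate.ndj < band.band_low and p < alpha and result.direction == "lower":
        category = "suppressor"
    return ScreenCall(
        genotype=genotype,
        category=category,
        ndj=estimate.ndj,
        delta_matched=delta_matched,
        delta_average=delta_average,
        p_value=p,
        test=result,
        breakpoints=breakpoints,
    )


@dataclass(frozen=True)
class ScreenReport:
    calls: tuple[ScreenCall, ...]
    band: ControlSummary
    summary: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Screen table ordered like a published modifier table."""
        records = []
        for call in self.calls:
            records.append(
                {
                    "genotype": call.genotype,
                    "breakpoints": call.breakpoints,
                    "ndj_percent": None if call.ndj is None else as_percent(call.ndj),
                    "delta_matched_percent": None
                    if call.delta_matched is None
                    else round_half_up(100 * call.delta_matched),
                    "delta_average_percent": None
                    if call.delta_average is None
                    else round_half_up(100 * call.delta_average),
                    "p_value": call.p_value,
                    "category": call.category,
                }
            )
        return pd.DataFrame.from_records(records)


def _position_key(call: ScreenCall, index: int):
    try:
        interval = cytomap.parse_interval(call.breakpoints)
        return (0, interval.possible_lo.key_low(), interval.possible_hi.key_high(), index)
    except Exception:
        return (1, (0, 0, 0), (0, 0, 0), index)  # unparsed rows keep input order at the end


def screen_report(
    rows: Iterable[CountTableRow],
    alpha: float = 0.05,
    band_multiplier: float = 1.0,
    p_adjust: Literal["fdr_bh"] | None = None,
    band: ControlSummary | None = None,
) -> ScreenReport:
    """Classify every non-control row of a screen table.

    Controls are the rows with no ``matched_control_id``; the band comes
    from their frequencies unless an external ``band`` is supplied (e.g.
    when retesting a handful of crosses against a previously summarized
    control series). Output is ordered enhancers first, then suppressors,
    then the rest, each group by cytogenetic position. ``p_adjust='fdr_bh'``
    applies a Benjamini-Hochberg correction across the tested rows before
    classification (off by default, matching the per-test 95% criterion
    screens conventionally use).
    """
    rows = list(rows)
    controls = [r for r in rows if r.is_control]
    tested = [r for r in rows if not r.is_control]
    control_by_id = {r.experiment_id: r for r in controls}
    if band is None:
        band = control_summary(
            [ndj_frequency(r.counts).ndj for r in controls],
            band_multiplier=band_multiplier,
        )

    # first pass: run the matched-control tests (needed before BH adjustment)
    raw: list[tuple[CountTableRow, ProgenyCounts | None]] = []
    for row in tested:
        control_row = control_by_id.get(row.matched_control_id)
        if row.status == "ok" and control_row is None:
            raise ConfigurationError(
                f"genotype {row.genotype!r}: matched_control_id "
                f"{row.matched_control_id!r} not among controls"
            )
        raw.append((row, None if control_row is None else control_row.counts))

    adjusted: dict[int, float] = {}
    if p_adjust == "fdr_bh":
        indices = [i for i, (row, ctrl) in enumerate(raw) if row.status == "ok"]
        pvals = [
            compare_to_control(raw[i][0].counts, raw[i][1], alpha=alpha).p_value
            for i in indices
        ]
        if pvals:
            adjusted = dict(zip(indices, multipletests(pvals, method="fdr_bh")[1]))
    elif p_adjust is not None:
        raise ConfigurationError(f"unknown p_adjust {p_adjust!r}")

    calls = []
    for i, (row, control_counts) in enumerate(raw):
        call = classify(
            genotype=row.genotype,
            counts=row.counts,
            matched_control=control_counts,
            band=band,
            alpha=alpha,
            status=row.status,
            breakpoints=row.breakpoints,
            p_value=adjusted.get(i),
        )
        logger.info(
            "%s: %s (ndj=%s, delta_matched=%s, delta_average=%s, p=%s)",
            call.genotype,
            call.category,
            call.ndj,
            call.delta_matched,
            call.delta_average,
            call.p_value,
        )
        calls.append(call)

    group_rank = {c: i for i, c in enumerate(CATEGORIES)}
    order = sorted(
        range(len(calls)),
        key=lambda i: (group_rank[calls[i].category], _position_key(calls[i], i)),
    )
    ordered = tuple(calls[i] for i in order)
    summary = {c: sum(1 for call in ordered if call.category == c) for c in CATEGORIES}
    logger.info(
        "screen summary: %s",
        ", ".join(f"{v} {k}" for k, v in summary.items() if v),
    )
    return ScreenReport(calls=ordered, band=band, summary=summary)
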
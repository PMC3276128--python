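"""Count-table TSV reading, validation, and writing.

The screen's exchange format is a UTF-8 TSV with a header naming, in any
order: ``genotype``, ``experiment_id``, ``matched_control_id``, ``normal``,
``exc_female``, ``exc_male``, ``status``, ``breakpoints``. Tab separation is
deliberate — breakpoint strings are rich in semicolons and genotype labels
in slashes, so no quoting is ever needed. Rows flagged ``sterile``/
``lethal``/``untested`` may leave the count cells empty (those are
phenotypic observations, not counts).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import TableFormatError
from .estimate import ProgenyCounts

STATUSES = ("ok", "sterile", "lethal", "untested")
REQUIRED_COLUMNS = ("genotype", "experiment_id", "normal", "exc_female", "exc_male")
OPTIONAL_COLUMNS = ("matched_control_id", "status", "breakpoints")
ALL_COLUMNS = REQUIRED_COLUMNS[:2] + OPTIONAL_COLUMNS[:1] + REQUIRED_COLUMNS[2:] + OPTIONAL_COLUMNS[1:]


@dataclass(frozen=True)
class CountTableRow:
    """One genotype scored in one experimental round."""

    genotype: str
    experiment_id: str
    normal: int | None
    exc_female: int | None
    exc_male: int | None
    matched_control_id: str = ""
    status: str = "ok"
    breakpoints: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise TableFormatError(
                f"unknown status {self.status!r} for genotype {self.genotype!r}"
            )
        has_counts = all(
            v is not None for v in (self.normal, self.exc_female, self.exc_male)
        )
        if self.status == "ok" and not has_counts:
            raise TableFormatError(
                f"status 'ok' requires counts (genotype {self.genotype!r})"
            )

    @property
    def counts(self) -> ProgenyCounts | None:
        if self.normal is None:
            return None
        return ProgenyCounts(self.normal, self.exc_female, self.exc_male)

    @property
    def is_control(self) -> bool:
        """Control rows are those not paired to any other row."""
        return self.matched_control_id == "" and self.status == "ok"


def _parse_count(cell: str, column: str, row_label: str, status: str) -> int | None:
    cell = cell.strip()
    if cell == "":
        if status == "ok":
            raise TableFormatError(f"row {row_label!r}: empty {column} with status 'ok'")
        return None
    try:
        value = int(cell)
    except ValueError:
        raise TableFormatError(
            f"row {row_label!r}, column {column!r}: {cell!r} is not an integer count"
        ) from None
    if value < 0:
        raise TableFormatError(f"row {row_label!r}, column {column!r}: negative count")
    return value


def read_count_table(path: str | Path) -> list[CountTableRow]:
    """Read and validate a count table; rejects duplicate (genotype, round) keys."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty file (no header)")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TableFormatError(f"{path}: missing required column(s) {missing}")
        rows: list[CountTableRow] = []
        seen: set[tuple[str, str]] = set()
        for record in reader:
            genotype = (record.get("genotype") or "").strip()
            experiment_id = (record.get("experiment_id") or "").strip()
            label = f"{genotype}/{experiment_id}"
            status = (record.get("status") or "ok").strip() or "ok"
            if status not in STATUSES:
                raise TableFormatError(f"row {label!r}: unknown status {status!r}")
            key = (genotype, experiment_id)
            if key in seen:
                raise TableFormatError(f"duplicate (genotype, experiment_id) {key}")
            seen.add(key)
            rows.append(
                CountTableRow(
                    genotype=genotype,
                    experiment_id=experiment_id,
                    normal=_parse_count(record.get("normal") or "", "normal", label, status),
                    exc_female=_parse_count(
                        record.get("exc_female") or "", "exc_female", label, status
                    ),
                    exc_male=_parse_count(
                        record.get("exc_male") or "", "exc_male", label, status
                    ),
                    matched_control_id=(record.get("matched_control_id") or "").strip(),
                    status=status,
                    breakpoints=(record.get("breakpoints") or "").strip(),
                )
            )
    return rows


def write_count_table(rows: Iterable[CountTableRow], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ALL_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.genotype,
                    row.experiment_id,
                    row.matched_control_id,
                    "" if row.normal is None else row.normal,
                    "" if row.exc_female is None else row.exc_female,
                    "" if row.exc_male is None else row.exc_male,
                    row.status,
                    row.breakpoints,
                ]
            )
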
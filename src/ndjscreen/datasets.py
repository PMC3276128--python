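"""Bundled example data: progeny counts from a published-scale modifier screen.

Three count tables from a third-chromosome deficiency screen for dominant
modifiers of *bubR1*-induced X-chromosome nondisjunction, plus the
breakpoint sets used to narrow candidate regions:

* :func:`control_experiments` — the sensitized *bubR1* genotype scored in
  each of 16 experimental rounds (the matched controls).
* :func:`deficiency_screen` — the 24 deficiencies called as modifiers, each
  paired with its round's control via ``matched_control_id``.
* :func:`polo_region_crosses` — the *polo*-region deficiencies and alleles
  retested against the round-10 control.
* :func:`region_mapping` — overlapping-deficiency breakpoints (positive and
  negative) for three candidate-region narrowing exercises.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import CountTableRow, read_count_table


def _data_path(name: str):
    return resources.files("ndjscreen.data").joinpath(name)


def _read_bundled(name: str) -> list[CountTableRow]:
    with resources.as_file(_data_path(name)) as path:
        return read_count_table(path)


def control_experiments() -> list[CountTableRow]:
    """The 16 control rounds of the screen (one genotype, 16 experiments)."""
    return _read_bundled("control_experiments.tsv")


def deficiency_screen() -> list[CountTableRow]:
    """The 24 modifier deficiencies with their matched-control pairing."""
    return _read_bundled("deficiency_screen.tsv")


def polo_region_crosses() -> list[CountTableRow]:
    """Retests of the 77B region: deficiencies and *polo* alleles vs round 10."""
    return _read_bundled("polo_region.tsv")


def screen_rows() -> list[CountTableRow]:
    """Controls plus deficiencies, ready for :func:`ndjscreen.screen.screen_report`."""
    return control_experiments() + deficiency_screen()


def region_mapping() -> pd.DataFrame:
    """Breakpoint sets for region narrowing; columns region/deficiency/breakpoints/effect."""
    with resources.as_file(_data_path("region_mapping.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str)
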
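"""End-to-end pipeline: estimate -> test -> classify -> (optional) map-region.

Configuration is a flat mapping (or a YAML file of one):

    counts: path to the count-table TSV
    alpha: 0.05
    band_multiplier: 1.0
    seed: 0
    output_dir: out/
    map_region: optional path to a deficiency/breakpoints/effect TSV

Outputs are deterministic TSVs (estimates, tests, screen) plus a run log
recording the seed, a hash of the configuration, and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, NdjScreenError
from .estimate import as_percent, ndj_frequency
from .hierarchy import ci_d, compare_to_control, fit_genotype
from .io import CountTableRow, read_count_table
from .screen import ScreenReport, screen_report
from .cytomap import candidate_region

logger = logging.getLogger(__name__)

_DEFAULTS: dict[str, Any] = {
    "alpha": 0.05,
    "band_multiplier": 1.0,
    "seed": 0,
    "ci_level": 0.95,
    "output_dir": "ndjscreen-out",
    "map_region": None,
}


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            source = yaml.safe_load(handle) or {}
    config = {**_DEFAULTS, **dict(source)}
    if "counts" not in config:
        raise ConfigurationError("config must name a 'counts' TSV path")
    return config


def estimate_table(rows: list[CountTableRow], ci_level: float = 0.95) -> pd.DataFrame:
    """Per-genotype viability-corrected estimates with Wilson intervals."""
    records = []
    for row in rows:
        counts = row.counts
        if counts is None or counts.survivors == 0:
            records.append({"genotype": row.genotype, "experiment_id": row.experiment_id,
                            "status": row.status})
            continue
        est = ndj_frequency(counts)
        lo, hi = ci_d(fit_genotype(counts), level=ci_level)
        records.append(
            {
                "genotype": row.genotype,
                "experiment_id": row.experiment_id,
                "status": row.status,
                "normal": counts.normal,
                "exc_female": counts.exc_female,
                "exc_male": counts.exc_male,
                "adjusted_total": est.adjusted_total,
                "ndj_percent": est.percent,
                "ci_low_percent": as_percent(lo),
                "ci_high_percent": as_percent(hi),
            }
        )
    return pd.DataFrame.from_records(records)


def test_table(rows: list[CountTableRow], alpha: float = 0.05, ci_level: float = 0.95) -> pd.DataFrame:
    """Matched-control comparison for every paired row."""
    control_by_id = {r.experiment_id: r for r in rows if r.is_control}
    records = []
    for row in rows:
        if row.is_control or row.status != "ok":
            continue
        control = control_by_id.get(row.matched_control_id)
        if control is None:
            raise ConfigurationError(
                f"{row.genotype!r}: matched_control_id {row.matched_control_id!r} unknown"
            )
        fit = fit_genotype(row.counts)
        lo, hi = ci_d(fit, level=ci_level)
        result = compare_to_control(row.counts, control.counts, alpha=alpha)
        records.append(
            {
                "genotype": row.genotype,
                "d_hat": fit.d_hat,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": result.p_value,
                "direction": result.direction,
                "method": result.method,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class PipelineResult:
    estimates: pd.DataFrame
    tests: pd.DataFrame
    report: ScreenReport
    regions: dict[str, str]
    output_dir: Path


def _config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def run_pipeline(source: str | Path | Mapping[str, Any]) -> PipelineResult:
    """Run every stage on a count table and write the report bundle."""
    config = load_config(source)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, func, *args, **kwargs):
        try:
            return func(*args, **kwargs)
        except NdjScreenError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    rows = stage("read", read_count_table, config["counts"])
    estimates = stage("estimate", estimate_table, rows, ci_level=config["ci_level"])
    tests = stage("test", test_table, rows, alpha=config["alpha"], ci_level=config["ci_level"])
    report = stage(
        "screen",
        screen_report,
        rows,
        alpha=config["alpha"],
        band_multiplier=config["band_multiplier"],
    )

    regions: dict[str, str] = {}
    if config["map_region"]:
        table = pd.read_csv(config["map_region"], sep="\t", dtype=str)
        group_col = "region" if "region" in table.columns else None
        groups = table.groupby(group_col) if group_col else [("all", table)]
        for name, group in groups:
            positives = group.loc[group["effect"] == "positive", "breakpoints"].tolist()
            negatives = group.loc[group["effect"] == "negative", "breakpoints"].tolist()
            regions[str(name)] = str(stage("map-region", candidate_region, positives, negatives))

    estimates.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    tests.to_csv(outdir / "tests.tsv", sep="\t", index=False)
    report.to_frame().to_csv(outdir / "screen.tsv", sep="\t", index=False)
    summary_line = ", ".join(f"{v} {k}" for k, v in report.summary.items() if v)
    log_lines = [
        f"ndjscreen {__version__}",
        f"seed: {config['seed']}",
        f"config_hash: {_config_hash(config)}",
        f"band: ({as_percent(report.band.band_low)}%, {as_percent(report.band.band_high)}%)",
        f"summary: {summary_line}",
    ]
    log_lines += [f"region {name}: {span}" for name, span in regions.items()]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    logger.info("pipeline complete: %s", summary_line)
    return PipelineResult(
        estimates=estimates, tests=tests, report=report, regions=regions, output_dir=outdir
    )
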
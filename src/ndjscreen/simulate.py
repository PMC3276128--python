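"""Seeded forward simulator of the scoring cross.

Each replicate draws a Poisson number of ova (matching the hierarchy
model's totals), assigns zygote classes by the segregation scheme, thins
each class by its viability, and reports the three scoreable progeny
classes. One global seed spawns independent per-replicate substreams, so
replicate *k* is reproducible without regenerating the first *k-1*.

The default expected ova per cross (1500) is of the magnitude real scoring
crosses of this design yield (a few hundred to a few thousand progeny).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .cross import (
    CrossModel,
    EXCEPTIONAL_FEMALE_CLASS,
    EXCEPTIONAL_MALE_CLASS,
    REGULAR_CLASSES,
    ZYGOTE_CLASSES,
    zygote_distribution,
)
from .errors import ParameterError
from .estimate import ProgenyCounts
from .io import CountTableRow

CONTROL_LABEL = "control"


@dataclass(frozen=True)
class SimulationConfig:
    """Replication plan for the cross simulator."""

    model: CrossModel
    lambda_total: float = 1500.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_total > 0:
            raise ParameterError(f"lambda_total={self.lambda_total!r} must be positive")
        if self.n_replicates < 1:
            raise ParameterError(f"n_replicates={self.n_replicates!r} must be >= 1")


def _simulate_one(model: CrossModel, lambda_total: float, rng: np.random.Generator) -> ProgenyCounts:
    probs = zygote_distribution(model)
    total = rng.poisson(lambda_total)
    zygotes = rng.multinomial(total, [probs[c] for c in ZYGOTE_CLASSES])
    viability = np.array([model.viability[c] for c in ZYGOTE_CLASSES])
    survivors = rng.binomial(zygotes, viability)
    by_class = dict(zip(ZYGOTE_CLASSES, survivors))
    return ProgenyCounts(
        normal=int(sum(by_class[c] for c in REGULAR_CLASSES)),
        exc_female=int(by_class[EXCEPTIONAL_FEMALE_CLASS]),
        exc_male=int(by_class[EXCEPTIONAL_MALE_CLASS]),
    )


def simulate_cross(config: SimulationConfig) -> list[ProgenyCounts]:
    """Simulate ``n_replicates`` independent scoring crosses."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    return [
        _simulate_one(config.model, config.lambda_total, np.random.default_rng(s))
        for s in streams
    ]


def simulate_screen(
    control_d: float,
    deficiency_effects: Mapping[str, float],
    config: SimulationConfig,
) -> tuple[list[CountTableRow], dict[str, str]]:
    """Simulate a full screen: one control round per deficiency.

    Each deficiency gets its own experimental round in which both the
    control cross (NDJ rate ``control_d``) and the deficiency cross (its
    entry in ``deficiency_effects``) are scored, mirroring the matched
    design. Returns the rows in count-table form plus the ground-truth
    category of every deficiency (from the true rates, not the counts).
    """
    for label, d in deficiency_effects.items():
        if not 0.0 <= d <= 1.0:
            raise ParameterError(f"deficiency {label!r}: d={d!r} outside [0, 1]")
    base = config.model
    rows: list[CountTableRow] = []
    truth: dict[str, str] = {}
    for round_idx, (label, d) in enumerate(deficiency_effects.items(), start=1):
        # per-round substream keyed by the round index: reproducible in isolation
        ctrl_stream, def_stream = np.random.SeedSequence(
            entropy=config.seed, spawn_key=(round_idx,)
        ).spawn(2)
        round_id = str(round_idx)
        ctrl_counts = _simulate_one(
            replace(base, d=control_d), config.lambda_total, np.random.default_rng(ctrl_stream)
        )
        def_counts = _simulate_one(
            replace(base, d=d), config.lambda_total, np.random.default_rng(def_stream)
        )
        rows.append(
            CountTableRow(
                genotype=CONTROL_LABEL,
                experiment_id=round_id,
                normal=ctrl_counts.normal,
                exc_female=ctrl_counts.exc_female,
                exc_male=ctrl_counts.exc_male,
            )
        )
        rows.append(
            CountTableRow(
                genotype=label,
                experiment_id=round_id,
                matched_control_id=round_id,
                normal=def_counts.normal,
                exc_female=def_counts.exc_female,
                exc_male=def_counts.exc_male,
            )
        )
        if d > control_d:
            truth[label] = "enhancer"
        elif d < control_d:
            truth[label] = "suppressor"
        else:
            truth[label] = "no_effect"
    return rows, truth
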
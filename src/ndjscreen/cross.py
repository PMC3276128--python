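"""Generative model of the X-nondisjunction scoring cross.

Females heterozygous for a nondisjunction-prone genotype are crossed to
``C(1;Y), v f B / O`` tester males. Each female meiosis missegregates the X
pair with probability ``d``; a nondisjunctional ovum is diplo-X (``XX``)
with probability ``p_xx`` and nullo-X (``O``) otherwise. Sperm carry the
compound ``C(1;Y)`` chromosome with probability ``sperm_cy`` (nullo
otherwise). The six zygote classes and their default fate:

=============  =======================  =========
zygote class   progeny phenotype        viability
=============  =======================  =========
X/C(1;Y)       regular female (Bar)     1
X/O            regular male (non-Bar)   1
XX/C(1;Y)      triplo-X                 0 (dies)
XX/O           exceptional female       1
O/C(1;Y)       exceptional male (v f B) 1
O/O            nullo-X                  0 (dies)
=============  =======================  =========

Half of the exceptional zygotes (the triplo-X and nullo-X classes) die,
which is exactly the lethality the downstream x2 count adjustment corrects
for. Viabilities are exposed per class so partial-viability scenarios are
testable; the defaults encode the binary scheme above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .errors import DegenerateModelError, ParameterError

#: Zygote classes in canonical order: maternal contribution / paternal one.
ZYGOTE_CLASSES: tuple[str, ...] = (
    "X/C(1;Y)",
    "X/O",
    "XX/C(1;Y)",
    "XX/O",
    "O/C(1;Y)",
    "O/O",
)

#: Classes countable in the progeny table (phenotypically distinguishable).
REGULAR_CLASSES: tuple[str, str] = ("X/C(1;Y)", "X/O")
EXCEPTIONAL_FEMALE_CLASS = "XX/O"
EXCEPTIONAL_MALE_CLASS = "O/C(1;Y)"

DEFAULT_VIABILITY: Mapping[str, float] = MappingProxyType(
    {
        "X/C(1;Y)": 1.0,
        "X/O": 1.0,
        "XX/C(1;Y)": 0.0,
        "XX/O": 1.0,
        "O/C(1;Y)": 1.0,
        "O/O": 0.0,
    }
)


def _check_unit_interval(name: str, value: float, open_ends: bool = False) -> None:
    lo_ok = value > 0 if open_ends else value >= 0
    hi_ok = value < 1 if open_ends else value <= 1
    if not (lo_ok and hi_ok):
        interval = "(0, 1)" if open_ends else "[0, 1]"
        raise ParameterError(f"{name}={value!r} outside {interval}")


@dataclass(frozen=True)
class CrossModel:
    """Parameters of the segregation/viability scheme.

    Parameters
    ----------
    d
        Nondisjunction rate per meiosis, in [0, 1].
    p_xx
        Fraction of nondisjunctional ova that are diplo-X rather than
        nullo-X, in [0, 1]. The observed excess of exceptional females over
        exceptional males can be represented by raising this above 0.5.
    sperm_cy
        Fraction of functional sperm carrying C(1;Y), in (0, 1).
    viability
        Per-zygote-class survival probability. Defaults to the binary
        scheme in the module docstring.
    """

    d: float
    p_xx: float = 0.5
    sperm_cy: float = 0.5
    viability: Mapping[str, float] = field(default_factory=lambda: DEFAULT_VIABILITY)

    def __post_init__(self) -> None:
        _check_unit_interval("d", self.d)
        _check_unit_interval("p_xx", self.p_xx)
        _check_unit_interval("sperm_cy", self.sperm_cy, open_ends=True)
        viability = dict(self.viability)
        unknown = set(viability) - set(ZYGOTE_CLASSES)
        if unknown:
            raise ParameterError(f"viability has unknown zygote classes: {sorted(unknown)}")
        for cls in ZYGOTE_CLASSES:
            _check_unit_interval(f"viability[{cls!r}]", viability.setdefault(cls, 0.0))
        object.__setattr__(self, "viability", MappingProxyType(viability))


@dataclass(frozen=True)
class ZygoteClassDistribution:
    """Probability distribution over the six zygote classes."""

    prob: Mapping[str, float]

    def __post_init__(self) -> None:
        prob = {cls: float(self.prob.get(cls, 0.0)) for cls in ZYGOTE_CLASSES}
        if any(p < 0 for p in prob.values()):
            raise ParameterError("zygote class probabilities must be nonnegative")
        total = sum(prob.values())
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"zygote class probabilities sum to {total!r}, not 1")
        object.__setattr__(self, "prob", MappingProxyType(prob))

    def __getitem__(self, cls: str) -> float:
        return self.prob[cls]


def zygote_distribution(model: CrossModel) -> ZygoteClassDistribution:
    """Distribution of zygote classes at fertilization (before viability).

    Regular classes carry probability ``1 - d`` split by the sperm ratio;
    exceptional classes carry ``d`` split by ``p_xx`` and the sperm ratio.
    """
    d, p, s = model.d, model.p_xx, model.sperm_cy
    return ZygoteClassDistribution(
        {
            "X/C(1;Y)": (1 - d) * s,
            "X/O": (1 - d) * (1 - s),
            "XX/C(1;Y)": d * p * s,
            "XX/O": d * p * (1 - s),
            "O/C(1;Y)": d * (1 - p) * s,
            "O/O": d * (1 - p) * (1 - s),
        }
    )


def surviving_distribution(model: CrossModel) -> ZygoteClassDistribution:
    """Distribution of zygote classes among surviving progeny.

    Each class is thinned by its viability and the result renormalized.
    With the default viability mask and an unbiased sperm ratio the
    exceptional fraction among survivors is ``(d/2) / (1 - d/2)`` — the
    odds parameter the hierarchical test operates on.
    """
    zygotes = zygote_distribution(model)
    weighted = {cls: zygotes[cls] * model.viability[cls] for cls in ZYGOTE_CLASSES}
    total = sum(weighted.values())
    if total <= 0:
        raise DegenerateModelError(
            "no zygote class has positive survival probability under this model"
        )
    return ZygoteClassDistribution({cls: w / total for cls, w in weighted.items()})


def expected_progeny_fractions(model: CrossModel) -> tuple[float, float, float]:
    """Expected (normal, exceptional-female, exceptional-male) fractions.

    Fractions are among *scoreable* survivors: classes that survive under a
    nondefault viability mask but are not one of the three countable
    phenotypes (e.g. partially viable triplo-X) are excluded, mirroring how
    such flies would not enter the progeny table.
    """
    surv = surviving_distribution(model)
    normal = sum(surv[c] for c in REGULAR_CLASSES)
    exc_f = surv[EXCEPTIONAL_FEMALE_CLASS]
    exc_m = surv[EXCEPTIONAL_MALE_CLASS]
    total = normal + exc_f + exc_m
    if total <= 0:
        raise DegenerateModelError("no scoreable progeny class survives under this model")
    return normal / total, exc_f / total, exc_m / total
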
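"""Multinomial-Poisson hierarchy likelihood for nondisjunction counts.

Model: a cross produces a Poisson(lambda) number of ova; each meiosis
missegregates the X pair with probability ``d``; zygote classes follow the
segregation scheme of :mod:`ndjscreen.cross` and are thinned by viability.
Poissonization makes the surviving class counts independent Poissons, so
conditional on the observed survivor total ``n_eff`` the exceptional count
is Binomial(n_eff, theta) with

    theta = (d/2) / (1 - d/2) = d / (2 - d),        d = 2*theta / (1 + theta).

The nuisance total lambda profiles out exactly; everything reduces to a
binomial likelihood in theta. The MLE d_hat coincides with the
viability-corrected count formula: 2E / (N + 2E).

Genotypes are compared by a likelihood-ratio test of equal theta (df=1).
When any expected cell of the 2x2 (exceptional, normal) x genotype table
falls below 5, the test switches to the exact conditional (Fisher) test. A
parametric bootstrap of the LR statistic is provided as a resampling check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.proportion import proportion_confint

from .errors import ParameterError, UndefinedEstimateError
from .estimate import ProgenyCounts

Direction = Literal["higher", "lower", "none"]
Method = Literal["lrt", "exact", "bootstrap"]


def theta_from_d(d: float) -> float:
    """Exceptional odds among survivors for NDJ rate ``d``."""
    return d / (2.0 - d)


def d_from_theta(theta: float) -> float:
    """Invert the survivor thinning: NDJ rate for exceptional odds ``theta``."""
    return 2.0 * theta / (1.0 + theta)


@dataclass(frozen=True)
class GenotypeLikelihood:
    """Binomial fit of one genotype's counts under the hierarchy model."""

    d_hat: float
    theta_hat: float
    loglik_at_mle: float
    n_eff: int
    exceptional: int

    @property
    def counts(self) -> tuple[int, int]:
        """(exceptional, normal) pair used by the 2x2 comparisons."""
        return self.exceptional, self.n_eff - self.exceptional


def _binom_loglik(e: np.ndarray | float, n: np.ndarray | float, theta) -> np.ndarray | float:
    # log-binomial kernel; the combinatorial constant cancels in all ratios
    return xlogy(e, theta) + xlogy(np.asarray(n) - np.asarray(e), 1.0 - np.asarray(theta))


def fit_genotype(counts: ProgenyCounts) -> GenotypeLikelihood:
    """Maximum-likelihood fit of theta (and hence d) for one genotype."""
    n_eff = counts.survivors
    if n_eff == 0:
        raise UndefinedEstimateError("cannot fit a genotype with zero surviving progeny")
    e = counts.exceptional
    theta = e / n_eff
    loglik = stats.binom.logpmf(e, n_eff, theta)
    return GenotypeLikelihood(
        d_hat=d_from_theta(theta),
        theta_hat=theta,
        loglik_at_mle=float(loglik),
        n_eff=n_eff,
        exceptional=e,
    )


def lr_statistic(e1, n1, e2, n2):
    """Likelihood-ratio statistic for H0: theta equal in two genotypes.

    Vectorized over numpy arrays; zero cells contribute 0*log(0) = 0.
    """
    e1, n1, e2, n2 = (np.asarray(x, dtype=float) for x in (e1, n1, e2, n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        th1 = np.where(n1 > 0, e1 / np.where(n1 > 0, n1, 1), 0.0)
        th2 = np.where(n2 > 0, e2 / np.where(n2 > 0, n2, 1), 0.0)
        th0 = (e1 + e2) / np.where(n1 + n2 > 0, n1 + n2, 1)
        stat = 2.0 * (
            _binom_loglik(e1, n1, th1)
            + _binom_loglik(e2, n2, th2)
            - _binom_loglik(e1, n1, th0)
            - _binom_loglik(e2, n2, th0)
        )
    return np.maximum(stat, 0.0)  # clip float noise at the boundary


@dataclass(frozen=True)
class TestResult:
    """Matched-control comparison of NDJ rates."""

    statistic: float
    p_value: float
    direction: Direction
    method: Method
    d_deficiency: float
    d_control: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _min_expected_cell(e1: int, n1: int, e2: int, n2: int) -> float:
    n = n1 + n2
    theta0 = (e1 + e2) / n
    return min(n1 * theta0, n1 * (1 - theta0), n2 * theta0, n2 * (1 - theta0))


def compare_to_control(
    deficiency: ProgenyCounts,
    control: ProgenyCounts,
    alpha: float = 0.05,
    method: Literal["auto", "lrt", "exact"] = "auto",
) -> TestResult:
    """Two-sided test of equal NDJ rate in a deficiency and its control.

    ``method='auto'`` uses the likelihood-ratio chi-square test and falls
    back to the exact conditional test when any expected cell of the 2x2
    table is below 5 (sparse-count regime where the chi-square
    approximation is unreliable). ``alpha`` is validated here for callers
    that immediately threshold the p-value.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha={alpha!r} outside (0, 1)")
    fit_d = fit_genotype(deficiency)
    fit_c = fit_genotype(control)
    e1, r1 = fit_d.counts
    e2, r2 = fit_c.counts
    statistic = float(lr_statistic(e1, fit_d.n_eff, e2, fit_c.n_eff))
    if method == "auto":
        method = (
            "exact"
            if _min_expected_cell(e1, fit_d.n_eff, e2, fit_c.n_eff) < 5
            else "lrt"
        )
    if method == "lrt":
        p_value = float(stats.chi2.sf(statistic, df=1))
    elif method == "exact":
        p_value = float(stats.fisher_exact([[e1, r1], [e2, r2]])[1])
    else:
        raise ParameterError(f"unknown test method {method!r}")
    if fit_d.theta_hat > fit_c.theta_hat:
        direction: Direction = "higher"
    elif fit_d.theta_hat < fit_c.theta_hat:
        direction = "lower"
    else:
        direction = "none"
    return TestResult(
        statistic=statistic,
        p_value=min(p_value, 1.0),
        direction=direction,
        method=method,
        d_deficiency=fit_d.d_hat,
        d_control=fit_c.d_hat,
    )


def ci_d(fit: GenotypeLikelihood, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for theta, mapped to the NDJ-rate scale.

    The map d = 2*theta/(1+theta) is monotone, so transforming the
    endpoints preserves coverage.
    """
    if not 0.0 < level < 1.0:
        raise ParameterError(f"level={level!r} outside (0, 1)")
    if fit.n_eff == 0:
        raise UndefinedEstimateError("confidence interval undefined for n_eff = 0")
    lo, hi = proportion_confint(
        fit.exceptional, fit.n_eff, alpha=1.0 - level, method="wilson"
    )
    return d_from_theta(float(lo)), d_from_theta(float(hi))


def bootstrap_p(
    deficiency: ProgenyCounts,
    control: ProgenyCounts,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Parametric bootstrap p-value for the matched-control comparison.

    Resamples under H0: both genotypes share the pooled theta-hat, with
    survivor totals drawn Poisson at each genotype's observed total
    (mirroring the Poisson hierarchy). The p-value uses the standard
    +1/(n_boot+1) correction so it is never exactly zero.
    """
    if n_boot < 1000:
        raise ParameterError(f"n_boot={n_boot} is too small for a stable p-value (need >= 1000)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit_d = fit_genotype(deficiency)
    fit_c = fit_genotype(control)
    observed = float(
        lr_statistic(fit_d.exceptional, fit_d.n_eff, fit_c.exceptional, fit_c.n_eff)
    )
    theta0 = (fit_d.exceptional + fit_c.exceptional) / (fit_d.n_eff + fit_c.n_eff)
    n1 = rng.poisson(fit_d.n_eff, size=n_boot)
    n2 = rng.poisson(fit_c.n_eff, size=n_boot)
    e1 = rng.binomial(n1, theta0)
    e2 = rng.binomial(n2, theta0)
    stats_boot = lr_statistic(e1, n1, e2, n2)
    exceed = int(np.count_nonzero(stats_boot >= observed - 1e-12))
    return (1 + exceed) / (n_boot + 1)
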
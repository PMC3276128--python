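"""Hierarchy-model fits, matched-control tests, intervals, bootstrap.

The exact-test oracle here enumerates all 2x2 tables with the observed
margins under the conditional (hypergeometric) null — fully independent of
the implementation path it checks.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndjscreen import (
    ProgenyCounts,
    bootstrap_p,
    ci_d,
    compare_to_control,
    d_from_theta,
    fit_genotype,
    ndj_frequency,
    theta_from_d,
)
from ndjscreen.errors import ParameterError, UndefinedEstimateError

from conftest import MODIFIER_TABLE


def exact_two_sided_oracle(e1: int, r1: int, e2: int, r2: int) -> float:
    """Conditional two-sided p by enumeration of tables with fixed margins."""
    row1, row2, col_e = e1 + r1, e2 + r2, e1 + e2
    lo, hi = max(0, col_e - row2), min(col_e, row1)
    weights = {x: math.comb(row1, x) * math.comb(row2, col_e - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    observed = weights[e1]
    # two-sided: sum tables no more probable than observed (tie tolerance as
    # in the standard implementations)
    return sum(w for w in weights.values() if w <= observed * (1 + 1e-7)) / total


nonzero_counts = st.builds(
    ProgenyCounts,
    normal=st.integers(1, 5000),
    exc_female=st.integers(0, 800),
    exc_male=st.integers(0, 800),
)


@given(counts=nonzero_counts)
@settings(max_examples=80, derandomize=True)
def test_mle_equals_count_formula(counts):
    fit = fit_genotype(counts)
    assert fit.d_hat == pytest.approx(ndj_frequency(counts).ndj, abs=1e-12)
    assert fit.d_hat == pytest.approx(d_from_theta(fit.theta_hat), abs=1e-12)
    assert math.isfinite(fit.loglik_at_mle)


def test_theta_d_transforms_are_inverse():
    for d in (0.0, 0.05, 0.25, 0.45, 1.0):
        assert d_from_theta(theta_from_d(d)) == pytest.approx(d, abs=1e-15)


@pytest.mark.parametrize(
    "counts, expected_pct, expected_theta",
    [
        ((725, 78, 18), 20.94, 96 / 821),
        ((500, 0, 0), 0.00, 0.0),
        ((0, 7, 5), 100.00, 1.0),
    ],
)
def test_fit_examples(counts, expected_pct, expected_theta):
    fit = fit_genotype(ProgenyCounts(*counts))
    assert round(100 * fit.d_hat, 2) == expected_pct
    assert fit.theta_hat == pytest.approx(expected_theta)


def test_fit_requires_survivors():
    with pytest.raises(UndefinedEstimateError):
        fit_genotype(ProgenyCounts(0, 0, 0))


def test_identical_counts_give_null_result():
    counts = ProgenyCounts(800, 90, 30)
    result = compare_to_control(counts, counts)
    assert result.statistic == 0.0
    assert result.p_value == 1.0
    assert result.direction == "none"


def test_label_swap_leaves_statistic_and_p_unchanged():
    a, b = ProgenyCounts(725, 78, 18), ProgenyCounts(1324, 178, 72)
    fwd, rev = compare_to_control(a, b), compare_to_control(b, a)
    assert fwd.statistic == pytest.approx(rev.statistic, abs=1e-12)
    assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
    assert {fwd.direction, rev.direction} == {"lower", "higher"}


def test_sparse_counts_switch_to_exact_and_match_enumeration():
    cases = [
        ((20, 5, 5), (40, 0, 0)),
        ((30, 1, 0), (25, 4, 3)),
        ((12, 2, 1), (50, 1, 0)),
        ((8, 0, 1), (9, 2, 2)),
    ]
    for def_counts, ctrl_counts in cases:
        d, c = ProgenyCounts(*def_counts), ProgenyCounts(*ctrl_counts)
        result = compare_to_control(d, c)
        assert result.method == "exact"
        oracle = exact_two_sided_oracle(
            d.exceptional, d.normal, c.exceptional, c.normal
        )
        assert result.p_value == pytest.approx(oracle, abs=1e-9)


def test_alpha_validated():
    counts = ProgenyCounts(100, 10, 5)
    with pytest.raises(ParameterError):
        compare_to_control(counts, counts, alpha=1.5)


def test_wilson_interval_behaviour():
    # boundary: zero exceptional progeny pins the lower limit at 0
    lo, hi = ci_d(fit_genotype(ProgenyCounts(270, 0, 0)))
    assert lo == 0.0 and 0.0 < hi < 0.05
    # point estimate inside its own interval
    fit = fit_genotype(ProgenyCounts(1869, 122, 64))
    lo, hi = ci_d(fit)
    assert lo < fit.d_hat < hi
    # interval is monotone in the confidence level
    lo90, hi90 = ci_d(fit, level=0.90)
    assert lo90 > lo and hi90 < hi
    # smaller samples give wider intervals in the same d region
    small = ci_d(fit_genotype(ProgenyCounts(61, 22, 4)))
    large = ci_d(fit_genotype(ProgenyCounts(610, 220, 40)))
    assert small[1] - small[0] > large[1] - large[0]


def test_all_modifier_rows_significant_vs_matched_control(
    deficiency_rows, controls_by_id
):
    for row in deficiency_rows:
        control = controls_by_id[row.matched_control_id]
        result = compare_to_control(row.counts, control.counts)
        assert result.p_value < 0.05, row.genotype
        expected = "higher" if MODIFIER_TABLE[row.genotype][4] == "enhancer" else "lower"
        assert result.direction == expected


def test_bootstrap_is_seeded_and_reproducible():
    a, b = ProgenyCounts(841, 281, 14), ProgenyCounts(2641, 280, 40)
    p1 = bootstrap_p(a, b, n_boot=2000, seed=11)
    p2 = bootstrap_p(a, b, n_boot=2000, seed=11)
    assert p1 == p2
    assert p1 < 0.01  # strongly divergent pair


def test_bootstrap_near_one_for_identical_large_counts():
    counts = ProgenyCounts(2000, 220, 80)
    assert bootstrap_p(counts, counts, n_boot=2000, seed=5) > 0.9


def test_bootstrap_rejects_tiny_resample_counts():
    counts = ProgenyCounts(100, 10, 5)
    with pytest.raises(ParameterError):
        bootstrap_p(counts, counts, n_boot=10)


def test_bootstrap_agrees_with_lrt_on_null_pairs():
    """Under H0 at moderate counts the chi-square and resampling p agree."""
    rng = np.random.default_rng(0)
    n_boot = 2000
    for _ in range(8):
        theta = rng.uniform(0.08, 0.2)
        n1, n2 = rng.integers(600, 2000, size=2)
        e1, e2 = rng.binomial([n1, n2], theta)
        a = ProgenyCounts(int(n1 - e1), int(e1), 0)
        b = ProgenyCounts(int(n2 - e2), int(e2), 0)
        p_lrt = compare_to_control(a, b, method="lrt").p_value
        p_boot = bootstrap_p(a, b, n_boot=n_boot, seed=rng.integers(2**31))
        mc_se = math.sqrt(max(p_boot * (1 - p_boot), 1e-6) / n_boot)
        assert abs(p_boot - p_lrt) <= 3 * mc_se + 0.01
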
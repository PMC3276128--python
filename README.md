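# ndjscreen

Analysis tools for *Drosophila melanogaster* X-chromosome nondisjunction
(NDJ) scoring crosses and the deficiency screens built on them.

## The problem

In a standard X-NDJ scoring cross, females carrying a meiotically
compromised genotype (here, *bubR1* trans-heterozygotes) are mated to
`C(1;Y), v f B / O` tester males. Dominant markers make every surviving
progeny class diagnostic: regular daughters are X/C(1;Y) (Bar), regular
sons X/O, exceptional daughters XX/O, exceptional sons O/C(1;Y). The
reciprocal exceptional classes — triplo-X (XX/C(1;Y)) and nullo-X (O/O) —
die, so half of all nondisjunctional zygotes are invisible. The
viability-corrected estimator counts each surviving exceptional fly twice:

```
adjusted total = normal + 2 (excF + excM)
X NDJ          = 2 (excF + excM) / adjusted total
```

Screening many deficiencies against this phenotype raises two further
questions the package answers:

1. **Is a deficiency's NDJ genuinely different from its control?** Scoring
   happens in rounds with different sample sizes and environments. Under a
   multinomial-Poisson hierarchy (Poisson ova, multinomial zygote classes,
   viability thinning), the exceptional count among the `n` survivors is
   Binomial(n, θ) with θ = d/(2−d), and d-hat = 2θ̂/(1+θ̂) is exactly the
   count formula above. Genotypes are compared by a df-1 likelihood-ratio
   test on θ against the round's matched control, with an exact conditional
   fallback for sparse tables and a parametric bootstrap as a resampling
   check.
2. **Where is the responsible gene?** Deficiency breakpoints are cytological
   (`66B12-C1;66D2-4`). Intersecting the possibly-deleted regions of
   modifier-positive deficiencies and subtracting the certainly-deleted
   bands of negatives narrows candidate regions to a few polytene bands.

A seeded forward simulator of the whole generative process (Poisson ova →
zygote classes → viability thinning → observed counts) makes every
statistical stage testable without fly work.

## Worked example

```python
from ndjscreen import ProgenyCounts, ndj_frequency, compare_to_control

deficiency = ProgenyCounts(normal=841, exc_female=281, exc_male=14)
control    = ProgenyCounts(normal=1782, exc_female=233, exc_male=33)

est = ndj_frequency(deficiency)
print(est.adjusted_total, est.percent)   # 1431 41.23
res = compare_to_control(deficiency, control)
print(round(res.statistic, 2), res.direction, res.p_value < 0.05)
# 81.8 higher True
```

The deficiency cross produced 841 regular and 295 exceptional flies, an
adjusted total of 1431 and an NDJ frequency of 41.23% — against 22.99% in
the matched control, a likelihood-ratio statistic of 81.8 (p ≈ 1.5e-19), so
the deficiency is a dominant enhancer of nondisjunction.

Running the bundled screen end to end:

```python
from ndjscreen import datasets, screen_report
report = screen_report(datasets.screen_rows())
print({k: v for k, v in report.summary.items() if v})
# {'enhancer': 6, 'suppressor': 18}
```

The `examples/` directory holds one short script per capability
(`reproduce_screen.py`, `single_comparison.py`,
`narrow_candidate_regions.py`, `simulate_and_recover.py`), and the `ndj`
command line exposes the same stages (`ndj estimate`, `ndj test`,
`ndj screen`, `ndj simulate`, `ndj map-region`, `ndj run`).

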
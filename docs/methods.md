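# Methods

## The scoring cross and the estimator

The package models a female X-NDJ scoring cross to `C(1;Y), v f B / O`
males. Per meiosis the X pair nondisjoins with probability `d`; a
nondisjunctional ovum is diplo-X with probability `p_xx` (default 0.5) and
nullo-X otherwise; sperm carry C(1;Y) with probability `sperm_cy` (default
0.5). Of the six zygote classes, triplo-X (XX/C(1;Y)) and nullo-X (O/O) are
lethal under the default viability mask; the four survivors are the
scoreable classes. Because exactly half of the exceptional zygotes die
(when `sperm_cy = 0.5`), each surviving exceptional fly represents two
nondisjunctional meioses, giving the x2-adjusted estimator

    d-hat = 2E / (N + 2E),   E = exceptional survivors, N = normal survivors.

Viability is a per-class probability rather than a binary mask so partial
viability scenarios can be explored; the defaults encode the binary scheme.
`p_xx` is exposed because real screen tables show a systematic excess of
exceptional daughters over sons; with an unbiased sperm ratio it changes
only the sex split of the exceptional class, not the estimator — a property
the test suite asserts. Whether that excess reflects ovum-class bias or
differential zygote recovery cannot be decided from count data; the model
exposes both knobs (`p_xx`, per-class viability) and takes no position.

## The hierarchy likelihood and the matched-control test

Totals vary enormously across crosses (hundreds to thousands), so raw
frequencies are not comparable without a sampling model. The package uses a
multinomial-Poisson hierarchy: the ova total is Poisson(λ), zygote classes
are multinomial given the total, and survival is Bernoulli per class. By
Poissonization the surviving class counts are independent Poissons, and
conditioning on the observed survivor total `n` removes λ exactly, leaving

    E | n  ~  Binomial(n, θ),    θ = (d/2) / (1 − d/2) = d / (2 − d).

θ is the natural testing scale (a canonical binomial parameter); `d` is the
reporting scale, recovered through the monotone map `d = 2θ/(1+θ)`. The
binomial MLE of θ transforms to exactly the x2-corrected count estimator,
which is why that estimator is the MLE of this model.

Two genotypes are compared with a likelihood-ratio test of equal θ
(df = 1, two-sided). When any expected cell of the 2x2
(exceptional, normal) x genotype table is below 5, the test switches to the
exact conditional (Fisher) test; in the bundled screen data the smallest
expected cell is 15.8, so every published comparison uses the LR test.
Interval estimates are Wilson score intervals on θ mapped through the
monotone transform. A parametric bootstrap (pooled θ̂, Poisson survivor
totals at the observed sizes, +1/(n_boot+1) correction) provides a
model-faithful resampling check of the LR p-values; the test suite verifies
agreement within Monte-Carlo error and verifies the exact fallback against
a full enumeration of 2x2 tables with fixed margins.

No multiple-testing correction is applied by default — the two-criterion
screen call deliberately mirrors the per-comparison 95% convention of
modifier screens — but `screen_report(p_adjust="fdr_bh")` provides a
Benjamini-Hochberg option.

### Control heterogeneity

The 16 bundled control rounds are mutually heterogeneous far beyond
binomial sampling error (e.g. the lowest round differs from the pooled rest
at |z| ≈ 6.6). This is expected — round-to-round environmental variation is
precisely why each deficiency is tested against the control of its own
round — but it means the control series must never be pooled into a single
binomial comparator, and the package does not offer that.

## The two-criterion classifier

A deficiency is called an enhancer (suppressor) only if

1. its unrounded NDJ frequency is strictly above (below) the control band,
   and
2. the matched-control test is significant at α (default 0.05) in the same
   direction.

The band is the control mean ± one sample SD (n−1 denominator; a
`band_multiplier` widens it). Band edges are computed from the two-decimal
percent summaries — 25.82 ± 4.87 → (20.95, 30.69) — because the printed
summaries are the operational thresholds of a screen; note that rounding
mean and SD before adding differs in the last digit from rounding their sum
(unrounded mean+SD is 30.684). Comparisons against the edges use unrounded
frequencies with strict inequalities: a genotype at 20.939% is below a
20.95% edge. One SD is an unusually permissive screen band; it is the
package default for fidelity to the screen design, not a recommendation.

Sterility and lethality are phenotypic status flags carried by the input
table; they override count-based classification and are never inferred from
counts.

### Printed-table rounding conventions

Published screen tables round to two decimals, half away from zero. The
bundled tables reproduce under these conventions, which the package adopts:

* the Δ-with-matched-control column is the *unrounded* frequency difference,
  then rounded for display;
* the Δ-with-average-control column is the difference of the *printed*
  (two-decimal) frequency and the printed control mean.

Both conventions were fixed by checking all 24 rows of the bundled table:
each reproduces its column exactly under its convention and not under the
alternative.

## Cytogenetic interval calculus

Breakpoint strings are parsed into intervals whose endpoints are
uncertainty ranges (`66B12-C1` → [66B12, 66C1]); a bare subdivision spans
the whole subdivision. Band order is lexicographic on (division,
subdivision, band). Strings with more than two breakpoints (complex
rearrangements) raise a distinct, skippable error.

Region narrowing intersects the positives' possible regions (earliest
proximal to latest distal bound, endpoints included) and subtracts each
negative's certain region — the bands *strictly between* its latest
proximal and earliest distal breakpoint bands. Keeping negatives'
breakpoint bands is uncertainty-conservative: a breakpoint band may be only
partially deleted, so a negative deficiency cannot exonerate it. The
subtraction may fragment the region; when it does, the retained breakpoint
slivers of negatives survive as separate fragments, and the operation
returns the largest fragment (most distal on ties). On the bundled
follow-up crosses this reproduces all three published candidate regions
(77B2;77C1, 94E9;94E11, 98A1;98A4); in the 98A case the discarded fragment
is exactly the two retained breakpoint bands (97F1-97F2) of two negatives.

Known inconsistency: for the 66C enhancer region the published narrowing
(66C6-66D4) implies the overlapping negative's distal breakpoint was read
as resolving to 66C5, whereas the conservative convention here keeps its
whole uncertainty range and yields 66C1;66D4. The package follows its
convention and documents the discrepancy rather than special-casing it.

Band numbers are validated up to 30 per subdivision (observed strings reach
66A20); subdivision sizes are never enumerated — whole-subdivision spans
use an open upper sentinel, which also nominally sizes fragments that cross
subdivisions.

## The simulator

`simulate_cross` draws Poisson ova totals (default λ = 1500, matching the
magnitude of real scoring-cross totals), multinomial zygote classes, and
per-class Bernoulli survival, reporting the three scoreable classes.
`simulate_screen` emulates the matched design: one simulated control round
per deficiency. One global seed spawns per-replicate substreams
(`numpy.random.SeedSequence`), so any replicate is reproducible in
isolation and identical seeds give identical tables.

What the simulator emulates: sampling noise, viability thinning, matched
pairing, Poisson total variation. What it does not: round-to-round
environmental heterogeneity (the simulated control SD is pure sampling
noise, so simulated bands are much narrower than the bundled empirical
band), maternal-age or brood effects, secondary nondisjunction, meiosis II
errors, and male meiosis. Passing calibration tests therefore certify the
statistics under the sampling model, not robustness to environmental
drift — which is what the matched-control design addresses in real data.

## Numerical choices and problem sizes

* Frequencies are stored as fractions; display rounds half away from zero
  to two decimals (`round_half_up`).
* LR statistics clip tiny negative float noise at zero; `0·log 0 = 0`.
* The type-I calibration suite runs 2000 simulated null rounds at d = 0.25,
  λ = 1000 (rejection rate must fall in [0.03, 0.07] at α = 0.05), and
  estimator-recovery runs use 800 replicates at λ = 2000 for
  d ∈ {0.05, 0.25, 0.45} with a |bias| < 0.005 criterion — sizes chosen so
  Monte-Carlo error is an order of magnitude below the tolerances.
* Bootstrap agreement checks use 2000 resamples and a 3 Monte-Carlo-SE
  tolerance against the asymptotic LR p-value on moderate-count pairs.
* Degenerate inputs raise typed errors: all-lethal viability masks
  (`DegenerateModelError`), zero adjusted totals
  (`UndefinedEstimateError`), single-control summaries
  (`InsufficientDataError`), inconsistent narrowing
  (`NoConsistentRegionError`).

## Limitations

* The hierarchy test conditions on survivor totals; it has no
  overdispersion term, so genuine environmental heterogeneity inflates the
  null rejection rate if controls are pooled across rounds (hence matched
  controls only).
* The interval calculus is cytological; it cannot exploit molecularly
  defined breakpoints or genome coordinates.
* Enhancer/suppressor sign conflicts between overlapping deficiencies
  (one region harboring both an enhancer and a suppressor) are resolved by
  the caller supplying effect-specific positive/negative sets; the package
  does not infer two-gene models.
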
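# Methods

## Model

A digital PCR chip partitions a reaction into `n` sub-volumes of volume `V`
(µL). Molecules land in partitions independently, so the count per partition
is Poisson with mean λ (copies/partition) and the negative fraction is
`q = e^{−λ}`. From an observed negative count `z` the maximum-likelihood
estimate is

    λ̂ = −ln(z/n),        C = λ̂ / V   (copies/µL).

The standard deviation of `ln λ̂` follows from the inverse Fisher
information of the binomial likelihood,

    σ = sqrt((e^λ − 1) / (λ² n)),

which gives a log-normal (multiplicatively symmetric, additively asymmetric)
confidence interval `λ·e^{±Zσ}` and the precision statistic

    P = max|1 − e^{±Zσ}| = e^{Zσ} − 1.

`P` is quasiconvex in λ with a unique minimum at the root of
`λ = 2(1 − e^{−λ})`, i.e. λ* ≈ 1.5936 (≈20.3% negatives), independent of
`n`; it deteriorates faster above λ* than below. The minimum partition
count for a target precision is the closed form
`n = ceil((e^λ−1)/λ² · (Z/ln(1+P))²)`, verified against the defining
inequality to absorb floating-point edge effects.

Two detection windows are provided: the *theoretical* window (≥1 positive to
≥1 negative at detection confidence 1−α), `λ_l = −ln(1−α)/n`,
`λ_u = −ln(1−(1−α)^{1/n})`; and the *precision-constrained* window, the two
roots of `P(λ) = bound` found by Brent's method on the monotone flanks
either side of λ* (relative tolerance 1e−12, well inside the 1e−9 the
window contract promises).

## False calls and system noise

Each true negative is miscalled positive with probability ε+ and each true
positive miscalled negative with probability ε− (independent per-class
flips), so the chip reports

    q_ε = q(1−ε+) + (1−q)ε−,     λ_ε = −ln q_ε.

Sampling spread is evaluated at λ_ε and pooled in quadrature with an
optional log-scale system noise σ_s. Precision is judged against the *true*
λ so the bias enters explicitly:

    P = max|1 − (λ_ε/λ)·e^{±Zσ_t}|,   σ_t = sqrt(σ_ε² + σ_s²).

A strict-additive variant `q_ε = q − ε+ + ε−` is available
(`model="additive"`) for sensitivity analysis; it becomes inconsistent once
`q < ε+` (high load), which is why the per-class model is the default. With
all rates zero every expression reduces exactly to the ideal model.

Consequences the tests assert: false positives dominate precision loss at
low λ and raise the lower limit of detection roughly tenfold at ε+ = 1%
(analytic LOD 0.0709 copies/partition at 20% precision and n = 20 000,
versus 0.0058 without noise); false negatives dominate at high λ and move
the precision optimum toward *more* negatives (lower load).

## Monte Carlo simulator

Partition volumes are drawn `Normal(V, cv·V)`, truncated below at
`1e−6·V` (a normal tail would otherwise produce unphysical non-positive
volumes; at cv ≤ 30% the truncation shifts the mean negligibly). Each
partition receives an independent `Poisson(C·v_i)` count — equivalent in law
to distributing a `Poisson(C·Σv_i)` total by volume-weighted multinomial
placement, an equivalence the test suite checks with a chi-square
comparison. False calls are applied per class after occupancy is decided.

Monodisperse, noise-aware chips without per-partition output use an exact
shortcut (`z ~ Binomial(n, e^{−λ})` with binomial flip counts); a rank test
against the per-partition path guards the equivalence.

Randomness: replicate `k` draws from the `k`-th child of
`SeedSequence(seed)`, so it is invariant to the total replicate count; each
grid point of a precision scan derives its own seed from `(seed, index)`.
Empirical precision is defined from the 2.5%/97.5% quantiles of λ̂ across
replicates (the 95% CI framing); saturated replicates are excluded and
counted rather than imputed, since the MLE is undefined at z = 0. Note the
quantile estimate is noisy at feasible replicate counts while the precision
curve is flat near λ*, so tests assert that the empirical argmin lies in
the flat bottom (analytic precision within 10% of the minimum) rather than
pinning a percent-negative value.

## Dilution planning

A step diluted 1:d covers `d·[λ_l/V, λ_u/V]` in original-sample copies/µL —
windows are compared in concentration units so steps with different
partition volumes compose correctly. Detection is *continuous* when
consecutive windows (sorted by factor) overlap; touching counts as
overlapping, making the paired boundary factor exactly `d* = λ_u/λ_l`. For
a gap-free plan the combined range is `log10(max upper / min lower)`;
otherwise only the covered logs are summed and the first gap is reported.
Serial plans under a fixed partition budget split it into equal subsets
(remainder discarded, conservative) and chain factors at the subset
boundary d*, which maximises range without creating gaps; replicate chips
at one dilution may be pooled by summing partitions since Poisson counts
pool exactly.

## Quantification pipeline

Chips are read from delimited summaries (a configurable column map, with a
ready-made QuantStudio-style layout), estimated per chip, pruned by the
fixed-order rule set described in the module docstring, and combined per
sample. Range rules (preferred 200–2000 copies/µL, high/low cutoffs 4600/9)
act on the chip's *measured* concentration; dilution correction (×d) is
applied for combination. The pair-fold rule compares the geometric means of
the two dilution groups with `|fold − 50|/50 ≤ 0.30`; the deviation measure
and the group-level pairing are our choices, since per-replicate pairing is
not recoverable from summary tables. As written the rule is near-vacuous —
two chips a true 50× apart can rarely both sit inside a 10× range — and it
fires only on genuinely inconsistent pairs, which is the intent.

Combination is inverse-variance weighting on the log scale (weights 1/σ²
with the per-chip sampling σ; optimal for log-normal CIs), with the
combined CI propagated as `1/sqrt(Σw)`; a plain geometric mean is available
via `method="mean"`. Rules are applied per chip before combination. Chips
that saturate (no negatives) or read all-negative are rejected with an
explicit audit reason; every input chip appears exactly once in the audit
table.

## Synthetic fixture

`generate_fixture` emulates a paired-dilution absolute-quantification
study: five samples in a 1:6.8 series (expected span 4·log10(6.8) = 3.330
logs), each paired 1:50 with three replicates, plus three NTCs — 33 chips
of 20 000 × 865 pl. The top concentration (80 000 copies/µL) was fixed once
so the series exercises the pruning rules realistically: the top undiluted
chips read far above the preferred range while their dilutions are
mid-range, the fourth sample is quantified undiluted, and the bottom sample
sits below range on both chips. False-call rates default to ε+ = 5·10⁻⁴
(≈10 NTC positives per chip) and ε− = 10⁻³. What the fixture does *not*
emulate: pipetting error in the dilution itself, chip-to-chip volume drift,
fluorescence thresholding, or spatial effects — so end-to-end recovery of
the 3.33-log span (asserted within ±0.05 logs for ≥18/20 seeds) validates
the statistics, not the wet-lab process.

## Problem sizes and numerics

Default test problem sizes — 2000-replicate calibration runs at n = 20 000
(exact binomial shortcut), 600–800-replicate volume-variability scans at
n = 2000–5000, and 10–20 seeded end-to-end runs — give Monte Carlo error
comfortably below the asserted tolerances. Confidence levels map to
z-scores through the exact normal quantile; `ConfidenceSpec(strict_paper=
True)` pins Z = 1.96 for reproducing conventionally printed values.
Degenerate inputs are typed errors, not sentinel values: saturated chips
raise `SaturatedChipError`, precision bounds below the achievable minimum
raise `UnachievablePrecisionError` carrying that minimum.

## Known limitations

- No bias-corrected or Bayesian λ estimators; the MLE is biased at very
  small expected positive counts, visible as a slight compression of deep
  series in the presence of false positives.
- False-call rates are user inputs; nothing is estimated from NTCs beyond
  the pass/fail ceiling.
- The additive error variant is provided for comparison only and is
  undefined at high load.
- Serial-plan factors are optimal only under the equal-subset, identical-
  volume assumption.
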
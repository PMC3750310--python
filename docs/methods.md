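# Methods

## Scope and data flow

The pipeline operates on three inputs: a per-food summary table
(concentration in mg/kg and intake in g/day, each summarized by
mean/std/median/P90 over 14 aggregated food categories), a scalar
configuration (tolerable intake, body weight, tobacco and water constants,
detection limit), and — optionally — an individual-level cohort table. The
bundled food table transcribes the Shanghai survey summaries; no
individual-level survey data was ever deposited, so the `cohort` module
generates synthetic cohorts with the same statistical structure for every
analysis that needs individuals.

Stages: deterministic point estimation (`point`), lognormal input fitting
(`distributions`), Monte Carlo propagation (`montecarlo`), contribution-to-
variance sensitivity (`sensitivity`), biomonitoring statistics
(`biomonitoring`), cohort synthesis (`cohort`), and a chaining pipeline/CLI.

## Point estimation

Units: mg/kg × g/day = μg/day throughout. The four summary levels multiply
(mean conc × mean intake), (median conc × median intake), (mean conc × P90
intake) and (P90 conc × P90 intake) per food and sum over foods. Two
conventions deserve note:

* **Median level.** The published per-food median exposures are consistent
  only with median-concentration × median-intake, so that is the default;
  the alternative mean-concentration convention is behind
  `median_uses_mean_conc=True`.
* **Missing P90 concentrations.** An absent cell is represented as absent,
  never zero. At the extreme level the resolution order is: P90
  concentration if present → per-food exposure override (the bundled
  override carries the tuber cell, whose P90 concentration was never
  printed) → normal-quantile fallback mean + 1.2816·std with a logged
  warning → error naming the food.

The smoking exposures at all four levels and the water exposures at the two
upper levels are survey-derived scalars that cannot be recomputed from the
summary food table; they ship as a small fixture used by the breakdown
(water mean/median is computed as concentration × volume = 0.025 × 1.2 =
0.03 μg/day). Reported tables round to two decimals; all internal
computation is full precision. When the breakdown is compared against the
published exposure table, agreement is within ±0.02 μg/day; the innard mean
and P90 cells differ by 0.011 and 0.013 because the published arithmetic
used unrounded intakes (0.278 × 0.5 = 0.139 prints as 0.15).

PTDI defaults to the printed 49.5 μg/day rather than being derived, because
the implied month length (25 × 60 / 49.5 ≈ 30.3 days) is nonstandard;
`derive_ptdi` reproduces it when given 30.3.

## Input distributions

All stochastic inputs are lognormal (the family reported as best-fitting for
every output model), with a point mass for zero spread and a
Bernoulli-lognormal mixture whose zero branch carries non-consumers or
non-smokers. Two parameterizations: method of moments on (mean, std) — used
for every per-food input, since the table prints std for each food — and
inversion of (mean, median) — used to reconstruct the *reported output*
distributions, since those print both. The two coincide exactly on
consistent moments of one lognormal. No goodness-of-fit testing is done and
no automatic family selection: the family is fixed by construction.

Self-consistency of the reported outputs: the lognormal implied by each
stratum's printed (mean, median) reproduces the printed std within 5% and
the printed 95th percentile within 6% for all five strata, but the printed
5th percentiles of the two lightest strata (women, non-smokers) are 25–30%
above the implied lower tail — the original simulations had lighter lower
tails than exact lognormals. The tests encode exactly these verified bounds.

Note the reconstructed probabilistic mean (23.05 μg/day total) exceeds the
point-estimate mean (16.73): the original input distributions were fit to
individual-level data that was never published, so the reported outputs are
not recoverable from the summary table alone. Reconstruction from printed
(mean, median) pairs is the supported path for risk probabilities.

## Monte Carlo engine

Independent draws for every input, within and across foods: no inter-food or
concentration–intake correlation is modelled because none was reported. This
tends to understate the variance of dietary exposure relative to a world
where high consumers of one staple are high consumers of another. The
tobacco term is Bernoulli(prevalence) × lognormal(cigarettes/day among
smokers, mean 9.2 and std 8.2 — back-solved from the smokers' daily dose of
13.8 ± 12.3 μg/day at 1.5 μg per cigarette-gram) × tobacco content ×
cigarette mass (1.0 g, configurable; not a printed value, chosen to make
1.5 μg/g × 9.2 cig/day reproduce the printed smokers' mean). The tobacco
content itself is stochastic — lognormal with mean 1.5 and std 1.0 μg/g, a
spread chosen once so the central 90% (≈0.5–3.4) spans the range commonly
cited for tobacco — so that sensitivity analysis can attribute variance to
it. Water is constant at 0.03 μg/day (half-LOD × 1.2 L). Smoking prevalences
default to 66.2% (men), 3.3% (women), 29.5% (total).

Defaults: n = 100,000 iterations, seed 42, PCG64 generator; percentiles use
linear interpolation between order statistics (immaterial at this n); std
uses the n−1 denominator. Determinism is bit-exact per (model, n, seed).

## Sensitivity

Contribution to variance = r_i² / Σ_j r_j² × 100 with r_i the Spearman rank
correlation between input i's draws and the output draws. Squared-rank
normalization makes the measure invariant under strictly monotone transforms
of any input, symmetric under input permutation, and zero for constant
inputs; the sign is reported separately. Regression-based and Sobol
alternatives are out of scope. Because the smoking Bernoulli is folded into
the "tobacco consumption" input (cigarettes actually smoked, zero for
non-smokers), in mixed strata that input absorbs most of the tobacco-branch
variance and the tobacco-content input is diluted by the non-smoking
fraction; the analysis therefore asserts the reported *ordering* (the two
tobacco inputs jointly outweigh any single food input; vegetable and rice
concentrations are the top two food inputs), not the exact printed
percentages, which depended on the original unpublished input fits.

## Biomonitoring statistics

LOD substitution replaces values strictly below the limit (or flagged) by
LOD/2; the boundary value is kept; the operation is idempotent. Mann–Whitney
U is the first group's U from rank sums with midrank ties, exact null
distribution for min(n₁,n₂) ≤ 8 without ties and the tie-corrected normal
approximation otherwise, always two-sided with a 0.05 significance
threshold. Correlation defaults to Pearson — the survey reported "R" without
naming a method — with Spearman available (and used inside the sensitivity
module regardless).

## Synthetic cohort

The generator emulates the study conditions: n = 207; 41.5% male; smoking
prevalence 66.2% / 3.3% by sex; ages uniform within the 40–59 and 60–90
bands with 37.2% in the upper band (only band fractions were published;
the within-band uniform is a modelling choice). Per-food intakes are
independent lognormals on the table moments, scaled 1.098× for men and
0.933× for women by default — factors solved from the published male/female
dietary means (14.0 vs 11.9 μg/day) under the 41.5% male mix, preserving the
overall mean. Disable with `sex_intake_scaling=False` to match the table's
std exactly (the scaling inflates per-food spreads by ~2%).

Internal doses follow structural models with multiplicative mean-one
lognormal noise:

    BCd = (b0_group + 0.02 · E_total) · ε,   ε ~ LN(−σ²/2, σ), σ = 0.741
    UCd = (u0 + 0.02 · age) · ε,                               σ = 0.826

The group intercepts are solved analytically from the published
smoker/non-smoker blood means (1.04 / 0.30 μg/L) and the expected exposure
given smoking status; u0 from the published urinary mean (1.88 μg/L) and
mean age. The slopes (0.02 μg/L per μg/day; 0.02 μg/L per year) are design
choices fixing how much of each dose is signal; the noise σs were then
solved by bisection on large cohorts so the population correlations hit the
published corr(E_total, BCd) ≈ 0.52 and corr(age, UCd) ≈ 0.15
(`calibrate_bcd_noise` / `calibrate_ucd_noise` reproduce them). What the
generator does **not** model: inter-food intake correlation, seasonality,
item-level (39-food) granularity, creatinine adjustment, or any dose–response
for health outcomes — so passing recovery tests show the pipeline's
statistics are consistent, not that real dietary data would satisfy the
independence assumptions.

## Numerical choices and degenerate inputs

Lognormal std uses expm1 to avoid cancellation at small coefficients of
variation; point-mass CDF treats the atom as included (CDF = 1 at the mass
point, with a 1e-12 relative tolerance for the exp/log round trip); mixture
quantiles return 0 for probabilities inside the zero mass. Zero total
dietary exposure makes contribution rates undefined (error, not NaN);
empty groups, zero-variance correlation inputs and all-constant sensitivity
inputs are rejected with named errors.

## Problem sizes

Simulations default to n = 100,000 draws (the published iteration count);
the test suite uses 50,000-person cohorts for moment-fidelity checks and 20
seeds × 207 participants for parameter recovery, sizes at which the
stochastic tolerances asserted (3 standard errors; ±0.15 on correlations)
are comfortably discriminating. The full suite runs in well under a minute.
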
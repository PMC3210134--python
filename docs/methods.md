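# Methods

## Biometric model

A phenotype is decomposed as P = A + C + D + E with variance
V_P = V_A + V_C + V_D + V_E. A pair of relatives is bivariate normal with a
common mean, both marginal variances V_P, and within-pair covariance
w_a·V_A + w_c·V_C + w_d·V_D, the weights fixed by the relation:

| relation | w_a | w_c | w_d |
|---|---|---|---|
| MZ twins | 1 | 1 | 1 |
| DZ twins | 1/2 | 1 | 1/4 |
| full brothers | 1/2 | 1 | 1/4 |

The additive weight is the expected fraction of segregating genes shared;
the dominance weight is the probability of sharing both alleles identically
by descent. Full brothers carry the same weights as DZ twins, which is what
lets a sibling register stand in for the (far smaller) twin sample once the
AE model is accepted.

Assumptions inherited from the classical design: equal environments for MZ
and DZ pairs, random mating, equal means and variances across zygosity
groups and pair order (testable here, see below), and no G×E *within* a
stratum — between-stratum changes in component magnitudes are exactly what
the cohort analysis is built to detect.

## Maximum-likelihood fitting

The joint log-likelihood over relation groups uses the exchangeable 2×2
structure, evaluated from per-group sufficient statistics (n, Σx_a, Σx_b,
Σx_a², Σx_b², Σx_a x_b), so cost is independent of the number of pairs once
the statistics are accumulated. The objective (negative log-likelihood per
pair, with analytic gradient) is minimized over (μ, path coefficients),
components entering as squared paths to enforce non-negativity. Multi-start
quasi-Newton (L-BFGS-B; default 5 starts: a method-of-moments start plus
seeded jitters) with function tolerance 1e-14 on the per-pair scale; a run
that stops in the line search with a projected gradient below 1e-6 per pair
is treated as converged. Models: ACE, ADE, AE, CE, E. ACE/ADE demand at
least two relation groups with distinct weights; requesting C and D together
is refused (not simultaneously identifiable from pairs reared together).

Model comparison is a likelihood-ratio chi-square with df equal to the
parameter difference, preferring the reduced model when p > α (parsimony
rule). The naive chi-square reference is used for the headline p-value even
when the constrained component sits on the boundary — matching standard
structural-equation practice — and for single-constraint comparisons the
50:50 mixture p-value (half the naive one for a positive statistic) is
reported alongside.

Confidence intervals: likelihood-profile by default (deviance crossing the
χ²₁ quantile, bisection on each raw component and each standardized share,
inner optimizations gradient-based with the fixed-share coordinate
eliminated by the chain rule); a seeded nonparametric pair-resampling
bootstrap (default B = 1,000) is available when raw pairs are supplied. The
method is tagged on the fit.

The equal-means-and-variances assumption test is an LRT of a saturated model
(per-group member means and free 2×2 covariance, 10 parameters; closed-form
MLE) against a constrained model (one mean and one variance shared across
groups and pair order, group-specific covariances, 4 parameters, numeric
fit), df = 6.

## Sibling cohort trend

All pair statistics are double-entry (ML intraclass): each pair contributes
both orderings, mean and variance are taken over the doubled sample with
divisor n, and the covariance is the mean cross-product of deviations from
the common mean. This makes results exactly invariant to within-pair
ordering and makes correlation ≡ covariance/variance, the identity the
decomposition h² = 2r relies on. Under the AE assumption V_A = 2·Cov,
V_E = V_P − V_A. A cohort correlation above 0.5 would drive V_A above V_P;
such rows are flagged inconsistent and reported uncapped (reports cap h² at
1, JSON keeps the raw value).

Cohorts are calendar birth years, each pair assigned the birth year of one
uniformly chosen member (seeded), so neither the elder nor the younger
brother defines the stratum; same-year pairs keep their year. Cohorts under
a minimum pair count (default 50) are skipped with a log entry; an optional
centred rolling window pools adjacent years for small synthetic runs.
Covariance/V_A/V_E intervals come from a seeded per-cohort pair bootstrap
(default B = 1,000, percentile, jointly propagated so the V_E interval
respects the V_A–V_E dependence); a delta-method interval is the fast
alternative. Correlation intervals are Fisher-z with the number of pairs
(not the doubled count) as effective sample size.

Filters mirror register practice and are configurable: both members must
have BMI strictly inside (15, 50) kg/m² — the plausibility window is
treated as strict exclusion of the endpoints — and pairs born more than 3
years apart (strict) are excluded. Families with k eligible sons contribute
all C(k,2) pairs; same-birth-year sibling sets pair as twins only when a
shared MZ or DZ label is present, are kept as full siblings when positively
labelled non-twin, and are dropped from both sets when zygosity is unknown
or conflicting. Duplicate person ids keep the first record.

## Prevalence and association

Obesity is BMI ≥ 30 (cut-point inclusive), prevalence computed per birth
year over all individuals with a Wilson score interval (Clopper–Pearson
optional). Trend association is the plain Pearson correlation between the
prevalence series and a component series joined on year (inner join),
Fisher-z interval with n = number of year points, plus the OLS slope of
component on prevalence with its t-test. No autocorrelation correction is
applied — the series are short and the estimand is descriptive — and
reports carry a note to that effect.

## Synthetic register generator

Pairs are generated by component construction: for additive weight w each
member's additive deviate is a shared N(0, w·V_A) draw plus an own
N(0, (1−w)·V_A) draw (likewise dominance with w_d; common environment fully
shared; unique environment independent), so marginal variances and
within-pair covariances match the target structure exactly and MZ/DZ/FS
samples are mutually consistent under one scenario. One master seed derives
deterministic per-operation child streams, so modules are testable in
isolation.

The cohort scenario assigns each generating year a component spec. The
bundled `swedish_conscript_scenario` is the package's reference condition:
birth years 1951–1983, V_A rising 4.3 → 7.9 kg²/m⁴ and V_E 1.4 → 2.0
(totals 5.7 → 9.9), piecewise-linear with a 1973 breakpoint so the rise is
moderate first and strong after; mean BMI drifting 21.0 → 22.4 kg/m²;
3,650 pairs per year mixed 97% FS, 1.4% MZ, 1.6% DZ — the register-scale
proportions (~116k sibling pairs, ~1.7k/1.9k twin pairs over 33 cohorts).
Full-sibling birth gaps are uniform on {0, 1, 2, 3} years (no empirical gap
distribution was available to calibrate against; the value is configurable),
the elder member chosen at random; twins share their year. The emitted pair
table stamps `cohort_year` with the generating year (the truth
stratification used by recovery tests), while the emitted individuals table
— one two-parent family per pair, so the pair set is exactly
reconstructible — retains the scattered birth years, and re-running the
random-brother cohort assignment reproduces the realistic blurring of
adjacent cohorts.

What the generator does not emulate: BMI right-skew (marginals are Gaussian
unless the lognormal option is on, in which case the spec lives on the log
scale), so Gaussian-tail obesity prevalences are lower than real-register
values at the same mean and variance and prevalence levels should not be
read against published figures — only the trend logic is meaningful;
within-family dependence between the C(k,2) pairs of larger sibships (each
synthetic pair is its own family; an option samples one pair per family for
real tables); assortative mating, age effects within the conscription
window, and any gap-dependent environmental drift between brothers. Passing
recovery tests therefore demonstrate estimator correctness under the stated
covariance structure, not robustness to those real-data features.

## Problem sizes and numerical choices

Recovery checks run at 100,000 MZ + 100,000 DZ pairs (twin ML fit,
standardized share tolerance ±0.01) and 500,000 FS pairs per calibration
(sibling estimator, tolerance ±0.05–0.1), sizes at which Monte-Carlo error
is comfortably inside the tolerances; replicated property studies
(type-I-error rates, CI coverage, selection rates) use 100–200 replicates
at a few hundred to a few thousand pairs each. Degenerate inputs are
errors, not silent results: singular expected matrices (V_E = 0 with unit
correlation), zero-variance strata, cohorts below the minimum size,
inverted BMI bounds, unknown relations. Ties in the largest-remainder
relation-mix rounding go to the largest fractional part; pair member order
on disk is lexicographic by id, which no statistic depends on.
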
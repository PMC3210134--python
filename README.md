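# twinvar

Twin and sibling-pair variance decomposition of body mass index (BMI):
maximum-likelihood ACE-family models for twin pairs, closed-form Falconer
estimators, and a cohort-stratified full-sibling decomposition of BMI
variance into additive-genetic and unique-environmental components — the
toolkit needed to ask whether the *genetic* variance of BMI has grown as the
obesogenic environment intensified.

It is aimed at quantitative-genetic and epidemiological analyses of large
sibling registers (conscription-style records with parent links and measured
height/weight), and ships a synthetic register generator so every analysis
can be exercised, calibrated and tested without access to restricted data.

## The model

The phenotypic variance of a trait is partitioned as

    V_P = V_A + V_C + V_D + V_E

(additive genetic, common environment, dominance, unique environment, the
last including measurement error). A relative pair is modelled as bivariate
normal with common mean, marginal variance V_P, and within-pair covariance

    Cov = w_a·V_A + w_c·V_C + w_d·V_D

with sharing weights fixed by the relation: MZ twins (1, 1, 1); DZ twins and
full brothers (1/2, 1, 1/4). Fitting MZ and DZ groups jointly by maximum
likelihood identifies the components; C and D cannot be estimated
simultaneously from pairs reared together, so ACE and ADE are fitted
separately and reduced models (AE, E) are tested by likelihood ratio with a
parsimony rule. Falconer's closed forms a² = 2(r_MZ − r_DZ),
c² = 2r_DZ − r_MZ, e² = 1 − r_MZ provide the moment-based cross-check.

Under an AE model, full-sibling pairs alone identify the components:

    V_A = 2·Cov(sib1, sib2),    V_E = V_P − V_A,    h² = 2·r

computed per birth cohort with the double-entry (ML intraclass) estimator,
which makes every statistic invariant to within-pair ordering and makes
r ≡ Cov/V_P exactly. The trend of V_A and V_E across birth years is then
correlated with obesity prevalence (BMI ≥ 30) per cohort. The utility
`locus_variance_contribution(p, a) = p(1−p)a²` gives the single-locus share
of V_A for reasoning about what a rising V_A can and cannot mean when the
gene pool is constant across cohorts.

## Worked example

Simulate a register-scale synthetic cohort series (33 birth years, ~3,650
pairs per year: 97% full brothers, 3% MZ/DZ twins; additive variance rising
4.3 → 7.9 kg²/m⁴ and unique-environment variance 1.4 → 2.0), then run the
full pipeline:

```sh
twinvar simulate  --out demo --seed 42
twinvar fit-twin  --pairs demo/pairs.csv --out demo/twin_fit.json --seed 42
twinvar sib-trend --pairs demo/pairs.csv --out demo/trend --seed 42 --bootstrap-b 200
twinvar prevalence --individuals demo/individuals.csv --out demo/prevalence.tsv
twinvar report    --dir demo
```

which prints, step by step:

```text
wrote 120450 pairs / 240900 individuals to demo
selected model: AE (std_a=0.778)
33 cohorts: var_a 4.00 -> 7.02, var_e 1.44 -> 2.23
prevalence 0.022% -> 1.333% over 36 years
report written to demo/report.json
```

and `demo/report.md` summarizes:

```text
- Selected twin model: **AE** (standardized A = 0.78)
- Additive genetic variance: 4.0 -> 7.0 kg²/m⁴
- Unique environmental variance: 1.4 -> 2.2 kg²/m⁴
- Total variance: 5.4 -> 9.3 kg²/m⁴
- Heritability (2·r, capped at 1): 73.4% -> 75.9%
- Obesity prevalence: 0.0% -> 1.3%
- Pearson r (prevalence vs V_A): 0.857
- Pearson r (prevalence vs V_E): 0.808
```

Reading: the twin analysis keeps the parsimonious AE model (standardized
additive share ≈ 0.78 at this twin sample size, ~1,700 MZ + ~1,900 DZ
pairs), licensing the sibling decomposition; the sibling trend recovers the
generating rise of the additive variance with its bootstrap CIs
(single-cohort estimates at ~3,500 pairs carry a sampling SE of ≈ 0.2–0.4
kg²/m⁴, visible in the endpoint readings above), and the genetic-variance
trend tracks obesity prevalence across cohorts. The same computations are
available as library functions (`twinvar.fit_model`, `twinvar.build_trend`,
`twinvar.prevalence_by_year`, …) on any pair table with columns
`relation,id_a,id_b,bmi_a,bmi_b,birth_year_a,birth_year_b,cohort_year`.

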
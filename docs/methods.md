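# Methods

This note records the statistical conventions the package implements, the
design of the synthetic data generator, and the choices made where the
methodology leaves room.

## Units, data model and validation

The unit of analysis is the household. All money fields of a dataset share
one currency and one accounting period (monthly); the three aggregates the
indicators need are total consumption expenditure (all twelve COICOP
divisions, health included), food expenditure, and out-of-pocket (OOP)
health expenditure. Because health is a component of the total, OOP budget
shares are ≤ 1 by construction and the data model enforces
`0 ≤ food ≤ total` and `0 ≤ oop ≤ total`. Invalid rows are rejected, not
imputed, each labelled with the first violated rule in a documented order;
validation is idempotent. Age enters only through two derived flags
(member under 5, member over 60) plus the head's activity, marital status
and education — exactly the covariates the determinants model uses.

## Catastrophic health expenditure

**Comparison convention.** Exceedance is strict (`>`) by default —
"exceeds" a threshold — with a non-strict option; boundary ties are
measure-zero in real data but must be deterministic in tests. A household
with zero denominator is catastrophic iff its OOP is positive (the share
is treated as infinite).

**Weighted percentiles.** The subsistence band uses cumulative-weight
inversion without interpolation: the p-th percentile is the smallest
observed value whose cumulative weight (values ascending, stable ties)
reaches p of the total. Band endpoints are closed. This makes the
subsistence proxy exactly reproducible by a hand scan, which the tests
exploit.

**Capacity to pay.** `ctp = total − se` when observed food spending is at
least the subsistence level `se`, and `ctp = total − food` otherwise (the
household spends less than subsistence on food, so its actual non-food
expenditure is the better measure of discretionary resources). The
published branch conditions for this rule are stated inconsistently in
parts of the literature; `literal_ctp_branches=True` applies the swapped
literal reading for sensitivity analysis. An optional equivalence scale
(`household_size**beta`, beta = 0.56 conventionally, off by default)
equivalises food spending before the band mean and re-scales per
household.

**Quintiles.** Households are ranked by per-capita (pre-OOP) total
expenditure; labels follow cumulative weight (boundaries at 20%, 40%, …),
and tied values all take the lowest applicable label, so a degenerate
distribution is all quintile 1. The quintile variable is recorded in
output metadata because different welfare rankings are defensible.

**Confidence intervals.** Wald normal approximation on the weighted
proportion with effective n equal to the unweighted stratum count, not
clamped to [0, 1]. Clamping would be easy but would break comparability
with the standard incidence tables this package mirrors, which print
negative lower bounds for sparse strata. No design-effect adjustment is
made for clustered samples; weights enter the point estimate only.

## Impoverishment and poverty gap

Poverty is strict: a household is poor when per-capita daily consumption
is `< z` (ties are "not poor"). The default line is US$3.1/person/day with
30 days/month; the exchange rate is an explicit user input (the synthetic
pipeline defaults to 35.8 rupees/US$, the value implied by a monthly
four-person household line of Rs 13,310 ≈ US$12.8/day ≈ US$3.1 per
person). Post-OOP consumption is `max(total − oop, 0)`; the floor is
defensive — canonical data cannot go negative. Averages are
household-weighted by default with a person-weighting flag
(weight × household size), since "share of households" and "proportion of
population" are both used in practice. With OOP ≥ 0 the impoverishment
increment equals the head-count difference exactly, and the post-OOP gap
dominates the pre-OOP gap; both identities are asserted in tests. Both the
increment and the two head counts are reported so a reader can also form
the conditional rate among the initially non-poor.

## Determinants model

The CHE flag at a chosen definition is the outcome; subsistence is
estimated *within* each survey year before pooling, then years are pooled
with year dummies (reference: earliest wave; if the nominal reference year
is absent the earliest present year becomes the reference so the design
stays full rank). Estimation is unweighted maximum likelihood via Newton
iteration (statsmodels `Logit`), convergence at relative log-likelihood
change < 1e−8 within 100 iterations, covariance from the inverse observed
information. Perfect separation (including a constant outcome or
coefficients diverging past ±50 on the logit scale) raises an explicit
error rather than returning a silently divergent fit; rank deficiency is
reported with the dependent column set from an SVD null space. Dummy
columns for factor levels absent from the data are kept and flagged,
never silently dropped. Inference is Wald throughout: OR = exp(coef),
CI = exp(coef ± z·se), two-sided normal p-values.

**Diagnostics.** The collinearity screen reports VIF = 1/(1 − R²) per
non-intercept column, with exact collinearity as infinite VIF plus the
dependency set. The Hosmer–Lemeshow test stable-sorts observations by
fitted probability (ties keep input order), forms g = 10 groups whose
sizes differ by at most one, sums (O − E)²/E over both outcome classes,
and refers the statistic to χ²(g − 2); a p-value requires g ≥ 3, and a
group with zero expected count in either class is an error. The χ²(g − 2)
reference is an approximation: with designs dominated by a handful of
discrete covariates the test runs conservative (simulated type-I error
around 2–4% at α = 5% for the full covariate design here, and lower still
for very coarse designs).

## Synthetic generator

The generator emulates the structure the indicators rely on; its defaults
are the study conditions used throughout the tests and the acceptance
script.

| parameter | default | why |
|---|---|---|
| n_households | 6,720 | the per-wave sample size of the three-wave HBS setting emulated |
| household size | 1 + Poisson(mean − 1); means 3.9/3.7/3.5 by wave | matches published mean sizes; variance ≈ mean with a hard minimum of 1 |
| urban share | 0.42 | Mauritius-like urbanisation |
| log total expenditure | Normal(10.2, 0.55), ×1.2 urban premium | Rs ≈ 27k/month median; urban disposable income reported ≥ 20% higher |
| food share | logistic⁻¹(3.15 − 0.40·log total + N(0, 0.35)) | Engel behaviour with shares guaranteed inside (0,1) |
| OOP | zero w.p. 0.35; else exp(6.5 + 0.8·(log total − 10.2) + δ·x + noise), capped at total | zero-inflated heavy right tail producing a few percent CHE; mean OOP share ≈ 5% |
| planted effects δ | elderly ln 1.756, retired ln 3.389 | the odds-ratio magnitudes the recovery experiments target |
| head demographics | wave-specific marginals (sex, marital, activity); under-5/over-60 presence = 1 − (1 − person share)^size | published person-level marginals converted to household presence under random mixing |

Covariates are drawn independently; real surveys correlate them (retired
heads co-occur with elderly members), so the generator understates
confounding. `oop_expenditure_elasticity` controls how the OOP *location*
scales with log expenditure: at the default 0.8 the OOP *share* declines
slightly with expenditure (flat-to-negative quintile gradient), while
values above 1 make health spending a luxury good and reproduce the
rich-spend-proportionally-more gradient seen in many settings; the
mechanism is exposed as a knob rather than asserted. The optional
two-stage design selects clusters with probability proportional to a
synthetic size frame, samples a fixed number of households per cluster,
sets weights to inverse inclusion probabilities, and adds a cluster
random effect (sd 0.2 on the log-expenditure scale).

All randomness comes from one `numpy` generator seeded by `seed`, drawn
in a fixed stream order, so identical parameters give field-identical
datasets.

**Recovery experiment.** `planted_effect_coverage` verifies estimation
end to end: with logistic-tailed OOP noise of unit log-scale, no zero
inflation, and the budget-share outcome, the induced CHE model is
*exactly* logistic in (elderly, retired, log total expenditure) with the
planted log-effects as true coefficients — the hard cap at total
expenditure cannot change a budget-share flag, and including log total
expenditure makes the fitted model correctly specified. Wald 95% CI
coverage of both planted effects over 100 replicates at n = 6,720 sits
inside [0.90, 0.99].

**What passing tests do and do not show.** The generator validates the
*computations* — flags, weighted estimators, identities, model recovery —
under known truth. It does not validate substantive conclusions about any
real population: real HBS data have correlated covariates, informative
weights, item non-response, reporting heaping, and intra-cluster
correlation beyond the simple random effect emulated here.

## Problem sizes

Simulation-based checks use sizes chosen to make their statistical
tolerances meaningful while keeping the default suite fast: oracle
equivalence on 1,000 households; monotonicity over 100 random surveys of
400; impoverishment identities over 20 surveys of 400; CI coverage over
100 replicates of 6,720; Hosmer–Lemeshow calibration over 200 replicates
of 5,000; quintile-gradient direction over 50 replicates of 1,200.

## Known limitations

- Variance estimation ignores the sampling design (no design effects,
  no replicate weights); CIs for clustered designs are anti-conservative.
- The weighted pseudo-likelihood option for the determinants model uses a
  naive variance; survey-weighted inference with linearised variance is
  out of scope.
- OOP reclassification questions (e.g. transport to care being recorded
  under transport rather than health) are upstream of this package: the
  three aggregates are taken as given.
- No Foster–Greer–Thorbecke measures beyond head count and gap, and no
  equivalence-scale poverty measurement.
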
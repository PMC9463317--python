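# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite can show.

## 1. Economic model of fertility

### One-period analytics

Agents maximize `U = u(Y) + aN`, `Y = (1 − bN)W`, with CRRA utility
`u(y) = (y^(1−σ) − 1)/(1 − σ)` (log utility taken as the limit when σ is
within 1e-9 of 1).  Parameters: `a` > 0 is the utility weight per child, `b`
∈ (0, 1) the time cost per child as a fraction of the working period, σ > 0
the curvature of the utility of income, `W` > 0 the wage.  The marginal
benefit of a child is `dU/dN = a − bW·u′(Y)`, and its response to the wage
decomposes into a negative substitution effect `−b·u′(Y)` and a positive
income effect `−bY·u″(Y)`; under CRRA the sum is `b(σ−1)Y^(−σ)`.  This
closed form is an exact identity, used as the oracle for the componentwise
computation (tolerance 1e-10) and cross-checked against central finite
differences of the marginal benefit (tolerance 1e-6, step 1e-5).

### Two-period model and solver

Period-1 time endowment 1 is split between education `s`, childcare `bN₁`
and work, so `Y₁ = 1 − s − bN₁` (period-1 wage normalized to 1); period 2:
`Y₂ = (1 − bN₂)·s·h`.  No borrowing: each period's income must be positive
on its own.  The objective `u(Y₁) + u(Y₂) + a(N₁+N₂)` is, for fixed `s`,
separable into two strictly concave one-dimensional problems whose interior
first-order conditions are `u′(Y₁) = a/b` and `u′(Y₂) = a/(b·s·h)`; both
have closed-form solutions with the corners at N = 0 handled explicitly.
The solver therefore reduces to a one-dimensional search over `s`: a dense
grid (1,025 points) locates the global basin — the value function can be
kinked where a corner activates — and bounded scalar minimisation polishes
the optimum to machine precision in `s`.  Incomes are floored at 1e-9
because CRRA utility is unbounded below (σ ≥ 1) or has an unbounded
derivative (σ < 1) as income → 0; the optimum is interior in income, so the
floor never binds at the solution.  An independent 64³ brute-force grid over
(N₁, N₂, s) serves as the oracle in the tests: over 100 random parameter
draws the solver's utility is never below the grid optimum minus 1e-4 (in
practice it is always above it).

### The five comparative-statics predictions

The claims concern dN*/dh, computed as a central finite difference (step
1e-3) of N* = N₁* + N₂*.  They are asserted on a default sweep
σ ∈ {0.8, 0.875, 0.95}, a ∈ {0.3, 0.6, 1.0}, b ∈ {0.05, 0.1, 0.15},
h ∈ {0.5, 1, 2, 4, 8} — σ below but near 1 is the regime where the
substitution effect dominates at low income and fades as income rises.  A
noise floor of 5e-4 on gradient magnitudes suppresses sign claims within
numerical noise.  Design choices made here, with their rationale:

1. **"dN*/dh negative"** is operationalized as *no gradient significantly
   positive and at least one significantly negative*.  At log utility the
   gradient is identically zero (analytically: Y₂/(s·h) = b/a and s* = b/a
   are independent of h), so a σ = 1 sweep fails this prediction — the
   knife-edge check — while near-zero gradients at high h within a σ < 1
   sweep do not spuriously fail it.
2. **Weaker at higher h**: |dN*/dh| weakly decreasing along every h-line.
3. **More negative at larger b**: compared along b-lines *within a fertility
   regime* (same N₁-corner status).  Across the corner transition the
   composition effect of prediction 5 takes over and can reverse the raw
   comparison; the default b-grid keeps fertility interior for the default
   `a` values.
4. **Weaker at higher education**: education is endogenous, so the test
   compares agents whose optimal s* differs *because their h differs*.
   Education variation induced by the child-preference parameter `a` moves
   education and fertility jointly and is not covered by the prediction (in
   fact it runs the other way: low-`a` agents study more *and* have steeper
   gradients); attributing across-person education differences to human
   capital matches the empirical device of splitting by realized education.
5. **Weaker among those postponing fertility** (N₁* = 0, classified at
   1e-6): compared as group means of |dN*/dh| within each (a, b, σ) slice.

## 2. Synthetic cohort generator

The generator emulates a biobank-style cohort — by default 409,629
respondents born 1938–1968 carrying 33 standardized scores — with every
quantity the downstream analyses estimate known by construction.

**Genetic architecture.**  One factor: score k satisfies
`z_k = ρ_k·HC + √(1−ρ_k²)·noise` with HC latent human capital, so
cross-score correlations are ρ_jρ_k and any |ρ| ≤ 1 vector is admissible.
Default ρ spans −0.35 … 0.5 (traits from negatively to strongly positively
earnings-linked).

**Two generations.**  Midparent score vectors (variance C/2) are drawn
first; respondent scores are midparent plus segregation noise with the same
factor structure, which reproduces the parent-generation law exactly.
Parental fertility follows the same link with the same γ (scalable), plus a
heritable non-score propensity (sd 0.25, transmitted with coefficient 1)
calibrated to give a parent–child RLRS correlation near 0.1.  Respondents
are sampled *as children* — proportionally to family size — deliberately
reproducing the size bias of a cohort recruited from offspring; sibship size
is parental children − 1.

**Fertility links.**  `linear`: E[n|z] = μ(1 + η); `poisson_log`:
E[n|z] = μ·exp(η); `econ_model`: the mean is N*(h) from the two-period
model with h = exp(0.5·HC) and parameters (a=0.4, b=0.25, σ=0.92), chosen
to give completed fertility near 1.7 and education near the model's optimal
schooling.  Counts are Poisson around the mean (μ = 1.9 for respondents,
2.3 for parents).  Default γ_k = −0.1·ρ_k: selection against
human-capital-linked scores, the mechanism under study.

**Ground truth.**  For the linear link the marginal slope of RLRS on score
k is (Cγ)_k exactly (γ_k itself for a single or uncorrelated scores); for
the log link it is computed by Gauss–Hermite quadrature over the
score-driven channel (cross-checked against large-n simulation); for the
economic link only simulation-based truth with a Monte-Carlo SE is offered.
Subgroup truths are exact when the stratifying variable is independent of
the scores.

**Mediation channel.**  Latent education `M = −u + τν` (u = Σγ_k z_k, τ =
0.5) is cut into an ordinal band at fixed normal quantiles (quartiles by
default); the *band* re-enters the fertility predictor alongside the direct
term, with both weights solved in closed form so that (i) each score's
marginal total effect is unchanged and (ii) a product-of-coefficients
mediation analysis on the generated data recovers exactly the configured
`mediation_frac`.  The algebra shows a single observed mediator can be
exactly calibrated for every score only when scores are exchangeable
(common |ρ| and |γ|); heterogeneous configurations spread per-score
proportions around the target (the closed-form per-score values are exposed
as `expected_mediation_proportions`; with the default 33-score mix the
median sits within 0.02 of the target).  Two further caveats, both
deliberate features of the design: size-biased sampling of respondents
perturbs the score distribution when parental fertility is score-linked,
shifting estimated proportions by roughly +0.015 at γ = −0.05, so
mediation-channel *validation* scenarios orthogonalize the parental channel
(`parent_gamma_scale = 0`); and subgroup multipliers correlated with scores
(via income) add a small approximation documented in the ground-truth
functions.

**Subgroup structure.**  Per-stratum multipliers scale the whole
score-driven predictor; defaults (income bands 1.6…0.4 low→high, stronger
effects for >median sexual partners and for respondents not living with a
partner) encode substitution-dominated selection concentrated in low-SES
strata.  Income bands are quintiles of `0.5·HC + noise`; education bands
quartiles of M.

**Other columns.**  AFLB (women with children only; missing otherwise) is
increasing in latent education — education delays first births — plus noise,
truncated to [14, 45]; optional hooks couple AFLB to scores and to
fertility for the two-channel (sign-flip) scenarios, off by default so the
mediation contract stays exact.  Risk attitude is a binary indicator
(26% prevalence) that predicts fertility (coefficient 0.05 SD) but is
independent of scores by default.  Lifetime partners are negative-binomial
with median 3; cohabitation is Bernoulli(0.7).

**Ascertainment.**  Participation is Bernoulli with log-odds
`logit(0.5) + strength·(edu_std + HC)/2` (default strength 0.5, an
abstraction of healthy-volunteer bias; the base rate is kept at 0.5 rather
than a realistic few percent so that pool sizes stay manageable).  The
sampling weight is the inverse participation probability; strength 0 gives
equal weights.  Because participation selects on education/human capital
and selection effects are stronger in low-SES strata, unweighted effects
are attenuated and weighting enlarges them — the qualitative pattern the
weighting correction is designed to reveal.  Scores are standardized
in-sample on the delivered cohort, as an analyst would receive them.

**Determinism.**  All draws flow from one `numpy` Generator seeded by
`seed`; a fixed seed yields byte-identical CSV output.

## 3. Selection scans

RLRS is normalized within exact birth year; birth years with zero mean
fertility cannot be normalized and are flagged (NaN) with a logged count,
never silently dropped.  The completed-fertility filter keeps males over 50
and females over 45 at the reference date (default 2010), ages by which
most childbearing has concluded.  Regressions are OLS, or WLS with the
sampling weights multiplying squared residuals; standard errors are
heteroskedasticity-robust (HC1) by default because RLRS is a ratio of
counts with strongly non-constant variance (classic SEs via
`se_type="classic"`).  Significance uses Bonferroni thresholds: α over the
number of scores scanned.  Subgroup scans reuse the weights in every
stratum when weighting is on.  The partner-count split places ties at the
median in the lower stratum, so the upper stratum is strictly "more than
median".  The median-percentage-difference summary between strata A
(reference, most-selected) and B is `median over qualifying scores of
100(|β_A|−|β_B|)/|β_B|`, where qualifying means significant in A at the
Bonferroni threshold with the same sign in all strata; an empty qualifying
set returns NaN.

## 4. Mediation

Product-of-coefficients with linear models: a-path `mediator ~ score`,
b-path and direct from `RLRS ~ score + mediator`; `total = direct +
indirect` is an exact identity for nested linear fits (asserted to 1e-10).
The mediator is the numeric ordinal education band (the proportion mediated
is invariant to affine recoding).  Percentile bootstrap over individuals
(default 100 resamples, i.i.d. rows, no stratification by birth year) gives
CIs for the indirect effect and the proportion; the proportion's CI is
flagged unbounded when bootstrap totals cross zero.  The indirect effect's
p-value uses the Sobel normal approximation — a 100-resample bootstrap
cannot resolve p-values at panel multiplicity thresholds (α over the number
of selected scores).  A proportion is flagged unstable when |total| <
5·SE(total).  Bootstrap CI coverage was verified at ~95% (within binomial
error over 200 replicates) at cohort size 3,000; at much smaller sizes the
percentile interval undercovers slightly, as percentile bootstraps do.

## 5. Inequality counterfactual

The child generation's score is the parent's score (transmission noise
ignored — consistent with using β as the expected child score); the unit is
the individual respondent.  Actual band means weight parents by child
counts; hypothetical means are unweighted.  The child-generation
score–income correlation is the frequency-weighted correlation (verified
identical to an exploded one-row-per-child table), with income as ordinal
band codes 1..K; the percentage change is flagged unstable when the
parental correlation is below 1e-3.  Equal fertility makes both
computations exactly invariant.

## 6. Problem sizes used in the acceptance script

Chosen to give tight Monte-Carlo error at desk scale: 200 random parameter
draws for the closed-form identity; 100 draws for the solver-vs-grid
comparison; 100 replicates at n = 50,000 each for recovery and null
calibration; n = 200,000 for subgroup and mediation recovery; 200
replicates at n = 3,000 (100 bootstrap resamples each) for CI coverage; a
200,000-respondent, 33-score cohort under the full default mechanism for
the study-conditions summaries.

## 7. What passing tests do and do not show

The generator reproduces the *structure* of the target data — two
generations, size-biased sampling, cohort normalization, banded covariates,
ascertainment weighting, subgroup-concentrated selection, a calibrated
education channel — but real cohorts differ in ways the tests cannot reach:
scores are noisy estimates with LD structure and ancestry confounding
(scores here are exact draws from the factor model); participation in real
studies selects on many more margins; assortative mating, indirect genetic
effects and gene–environment correlation are absent; fertility is not
Poisson around a smooth link; and band definitions are conventions, not
reproductions of any survey instrument.  Recovery of ground truth here
validates the estimators and their implementation, not the substantive
conclusions one would draw from any particular real dataset.
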
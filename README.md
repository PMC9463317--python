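# selgen — natural selection on polygenic scores via fertility differentials

`selgen` studies contemporary natural selection in biobank-style cohorts: the
association between standardized polygenic scores (PGS) and relative lifetime
reproductive success, why that association concentrates in particular social
subgroups, and what it does to the distribution of scores across income
groups in the next generation.  It is written for population geneticists and
social scientists who want a tested, fully synthetic-data-driven
implementation of this analysis — the real cohorts it emulates (hundreds of
thousands of genotyped participants with fertility histories) are access
restricted, so the package ships a generator with known ground truth instead.

## The statistic and the model

**Selection effect.**  For individual *i* with number of children *n_i*,
relative lifetime reproductive success is

    RLRS_i = n_i / mean(n_j : j born in the same year),

so RLRS averages 1 in every birth cohort.  The selection effect of a score is
the slope β in

    RLRS_i = α + β · PGS_i + ε_i.

Because scores are standardized, β is the selection differential and — within
a cohort, with in-sample standardization — is *algebraically* the
child-weighted mean score Σ n_i z_i / Σ n_i, i.e. the expected score among
the children of the sample (a Robertson–Price-style identity that the test
suite checks to 1e-10).

**Economic model of fertility.**  Why would earnings-linked scores be under
selection?  Agents maximize `U = u(Y) + aN` with CRRA utility
`u(y) = (y^(1−σ) − 1)/(1 − σ)`, where children take time `b` each and
`Y = (1 − bN)W`.  A wage rise moves the marginal benefit of a child by

    d²U/dNdW = −b·u′(Y)  [substitution effect, < 0]
             − b·Y·u″(Y) [income effect, > 0]
             = b(σ−1)·Y^(−σ)  under CRRA,

so at log utility (σ = 1) the two cancel exactly, and for σ < 1 the
substitution effect dominates: human capital *reduces* fertility.  A
two-period extension with an education choice `s` (period-2 wage `w = s·h`,
no borrowing) is solved numerically and yields five comparative-statics
predictions about the fertility–human-capital gradient dN*/dh — negative,
weaker at high h, stronger at high child-cost b, weaker at high education,
weaker among those who postpone fertility — all verified on a parameter
sweep.

Around this core the package implements: weighted (ascertainment-corrected)
and subgroup scans, cross-generation effects from sibship sizes, mediation
of selection effects by educational attainment (product-of-coefficients with
bootstrap CIs), and the counterfactual inequality computation
(child-weighted versus equal-fertility score means by income band, and the
selection-induced change in the score–income correlation).

## Worked example

```python
from selgen.pipeline import RunConfig, run_pipeline
from selgen.simulate import GeneratorConfig

cfg = RunConfig(
    out_dir="demo_run",
    generator=GeneratorConfig(n=20_000, n_scores=5, seed=11),
)
manifest = run_pipeline(cfg)
for line in manifest["log"]:
    print(line)
```

prints (in a couple of seconds):

```
simulate: generated 20000 rows
completed-fertility filter: retained 15946, excluded 4054
scan: mean % change from weighting = 10.5; 4 significant (weighted)
mediate: {'n_selected': 4, 'indirect_threshold': 0.0125, 'n_significant_same_sign_indirect': 4, 'median_proportion_mediated': 0.22424239201347268}
inequality: 5/5 score-income correlations amplified
model-check: predictions passed = {1: True, 2: True, 3: True, 4: True, 5: True}
```

Reading the output: 4,054 respondents too young for completed fertility are
excluded; correcting for ascertainment (inverse-participation weights) makes
effect sizes on average 10.5% larger; 4 of 5 scores show Bonferroni-significant
selection; about 22% of those effects run through educational attainment
(the generator's configured fraction is 25%, recovered up to sampling noise
at this cohort size); child-weighting increases the score–income correlation
for every score; and the economic model's five comparative-statics
predictions all hold on the default parameter sweep.

The same stages are available as CLI subcommands:

```bash
selgen simulate --n 20000 --n-scores 5 --seed 11 --out cohort.csv
selgen scan --input cohort.csv --split income --out scan_income.csv
selgen mediate --input cohort.csv --out mediation.csv
selgen inequality --input cohort.csv --out inequality.csv
selgen model-check --out predictions.csv
selgen run --config run.yaml
```

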
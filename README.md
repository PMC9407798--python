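# bcscreen

Personalized breast-cancer-screening risk estimation for 40–50-year-old
women: a reusable implementation of the risk pipeline used in
risk-stratified screening studies, plus the statistics for evaluating such
a trial's primary outcomes.

**Who it is for.** Biostatisticians and screening-program analysts who need
to (1) estimate a woman's 5-year absolute breast-cancer risk from classical
risk factors, (2) refine it with a polygenic risk score (PRS), (3) map the
final risk to a screening-frequency recommendation, and (4) summarize
acceptability/intention/satisfaction outcomes with exact binomial inference
— all runnable offline on synthetic cohorts.

## The model

1. **Combined relative risk.** Each woman's classical factors (BI-RADS
   density a–d, first-degree family history, benign breast disease,
   ethnicity) multiply into a relative risk *r* versus the lowest-risk
   profile, BCSC-v2-style. The attributable-risk fraction
   `1 − AR = 1 / E[r]` (expectation over the population category
   distribution) deflates composite incidence to the baseline hazard, so
   that model-average risk matches raw incidence: `E[r·(1 − AR)] = 1`.

2. **Absolute risk with competing mortality.** With piecewise-constant
   1-year hazards — breast-cancer incidence h₁ and competing mortality h₂ —
   the 5-year absolute risk is the cause-specific cumulative incidence

   ```
   AR(a, a+5) = Σⱼ  h₁*ⱼ r / (h₁*ⱼ r + h₂ⱼ)
                · (1 − e^{−(h₁*ⱼ r + h₂ⱼ)Δⱼ})
                · e^{−Σ_{k<j} (h₁*ₖ r + h₂ₖ)Δₖ},      h₁*ⱼ = h₁ⱼ (1 − AR)
   ```

   evaluated with the exact per-band closed form (no quadrature).

3. **Polygenic update.** The PRS over an 83-SNP panel is a composite
   likelihood ratio: per SNP, `LR(g) = OR^g / E[OR^G]` with
   `G ~ Binomial(2, p)` under Hardy–Weinberg equilibrium, multiplied across
   SNPs (population mean 1 by construction). The Bayesian update acts on
   the risk odds: `posterior odds = prior odds × PRS`.

4. **Recommendation.** Strict thresholds on the final risk: referral above
   6%, annual above 1.16% (ages 40–44) or 1.19% (otherwise — the average
   risks of 60- and 65-year-old women), then biennial/triennial bands, and
   watch-and-wait until the population program invitation — never issued at
   age ≥ 50.

5. **Trial outcomes.** Three-item attitude scale (positive when the 3–15
   total is ≥ 12), intention dichotomized as definitely-will/likely,
   satisfaction; proportions with Clopper–Pearson 95% CIs; the
   `n = ceil(z²p(1−p)/w²)` sample-size rule.

The bundled hazard and relative-risk tables are editable stand-ins (the
hazard table is calibrated so the average risks at 60 and 65 equal the
annual-screening thresholds); real deployments inject registry tables and
published coefficients through the same CSV interfaces.

## Worked example

```python
import numpy as np
import bcscreen as bc
from bcscreen.io import profiles_to_frame

woman = bc.RiskFactorProfile(woman_id="w001", age=47.3, family_history=True,
                             benign_disease="none", density="c")
gail = bc.GailRiskEstimator().fit()          # bundled default tables
X = profiles_to_frame([woman])
rr = gail.relative_risk(X)[0]                # 4.55
prior = gail.predict(X)[0]                   # 0.0179  (1.79% 5-year risk)
pop = gail.population_risk([woman.age])[0]   # 0.0096  (0.96% at her age)

panel = bc.example_panel()                   # 83 SNPs
g = np.random.default_rng(12).binomial(2, panel.frequencies)
prs = bc.composite_prs(g.tolist(), panel)    # LR = 0.591 over 83 SNPs
post = bc.bayes_update(prior, prs)           # 0.0107

print(bc.risk_report(bc.RiskResult("w001", rr, prior, prs.value, post, pop,
                                   bc.recommend(post, woman.age))))
```

which prints:

```
Woman w001
  Your 5-year breast cancer risk: 1.07% (11 of 1000 women like you)
  Average risk at your age: 0.96% (10 of 1000 women your age)
  Recommendation: Biennial screening mammogram recommended.
```

Her dense breasts and family history put her combined relative risk at 4.55
and her preliminary 5-year risk at 1.79% — above the 1.19% annual-screening
cut. Her genotype carries fewer risk alleles than average (PRS 0.59 < 1),
so the update lowers the final risk to 1.07%, moving her to biennial
screening; the pictogram counts (11 vs 10 per 1000) are what she would be
shown at the risk-communication visit.

The same flow is scriptable from a shell:

```bash
bcscreen simulate --n 400 --seed 7 --out-dir run/
bcscreen estimate --cohort run/cohort.csv --genotypes run/genotypes.csv \
                  --panel run/panel.csv --out run/results.csv
bcscreen outcomes --survey run/survey.csv --out run/outcomes.csv
bcscreen report --results run/results.csv
```

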
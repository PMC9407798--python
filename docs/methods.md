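# Methods

## Absolute-risk engine

The core quantity is the cause-specific cumulative incidence of breast
cancer over a horizon T (default 5 years) in the presence of competing
mortality. Hazards are piecewise-constant on closed-open 1-year age bands
[a, a+1); a fractional start age splits the first band. On each sub-interval
with constant breast-cancer hazard h₁* r and competing mortality h₂, the
probability of a breast-cancer event is
(h₁*r / (h₁*r + h₂)) · (1 − e^{−(h₁*r+h₂)Δ}), discounted by the survival
(event-free) probability accumulated over earlier sub-intervals. This is the
exact solution of the two-cause competing-risk ODE for piecewise-constant
hazards, so the engine carries no quadrature tolerance; the test suite
cross-checks it against an independent trapezoidal quadrature of
∫ h₁*(t) S(t) dt on a 10⁻⁴-year grid (agreement ≲ 10⁻¹²).

The relative risk r is applied age-constant across the window. The baseline
hazard is obtained from composite incidence by the attributable-risk
deflation h₁* = h₁(1 − AR) with 1 − AR = 1/E[r], the expectation taken over
the population category distribution.

### Calibration identity and its second-order limit

E[r(1 − AR)] = 1 holds exactly on the hazard scale (tested to 10⁻⁹). On the
absolute-risk scale the transform is concave in r, so averaging personal
risks over the prevalence distribution undershoots the raw-incidence
population risk by approximately (Λ²/2)·var(r(1 − AR)), with Λ the 5-year
baseline cumulative hazard. At screening-age hazard levels (Λ ≈ 0.01) this
is ~10⁻⁵ absolute — negligible for practice and covered by the cohort-level
Monte-Carlo calibration test, but not literally zero; tests assert the
hazard-scale identity exactly and the absolute-scale identity to 10⁻⁵.

## Relative-risk model

Factors multiply (density, family history, benign disease, ethnicity), as in
Gail-type models; the joint prevalence distribution used for AR is the
product of the per-factor marginals because no joint table is available —
a documented approximation that ignores real-world correlation between,
e.g., density and benign disease. Family history is binary (≥ 1 first-degree
relative). "Unspecified benign lesion" is carried as its own category and
mapped in the default table to a modest non-proliferative-scale relative
risk. Age-dependent coefficients are supported through an `age_group` key;
the bundled table is age-constant.

The bundled coefficients are implementer-transcribed values on the scale of
published density/family-history/benign-disease effects (density d = 3.35
vs a; family history 1.75; benign categories 1.25–3.0). They are explicitly
replaceable defaults: every test that needs exact numbers builds its own
synthetic table, and cohort-level checks on the defaults are band checks
(median combined rr within [1.5, 4.5]).

## Default hazard table

No registry life table ships with the package. The bundled table covers ages
[40, 90): competing mortality is Gompertz, 6×10⁻⁴·e^{0.085(age−40)} deaths
per person-year (female all-cause mortality net of breast cancer, mid-band);
incidence ramps linearly from 1.2×10⁻³ at 40, is constant on [60, 65) and
[65, 70) at levels solved by root-finding so the population 5-year risks at
ages 60 and 65 equal exactly 1.16% and 1.19%, and plateaus beyond 70. Those
two anchors are the semantics the screening policy depends on: the annual
thresholds are defined as the average risks of 60- and 65-year-old women, so
the bundled table keeps the policy's meaning testable offline. Absolute
levels elsewhere are Southern-European plausibility, not registry truth.

## Polygenic score

Per SNP the likelihood ratio is OR^g normalized by its Hardy–Weinberg
expectation E[OR^G] = (1−p)² + 2p(1−p)OR + p²OR², which forces population
mean 1 for any (p, OR) — the property that keeps the Bayesian update
calibration-preserving. The composite score multiplies per-SNP ratios,
assuming linkage equilibrium and independence from the classical factors;
both assumptions are standard for this construction and both are
limitations (no LD pruning, no ancestry recalibration). Missing genotypes
contribute factor 1 — the population-average likelihood — which is unbiased
under HWE and keeps every woman scoreable; `n_snps_used` reports coverage.

The update multiplies the 5-year-risk odds, not the instantaneous hazard:
posterior = oL/(1+oL) with o = risk/(1−risk). For risks of order 1% the two
formulations differ only in the third decimal of the percentage. A
consequence worth noting: because the update is convex in L at fixed prior,
the population-mean posterior is very slightly below the mean prior (of
order E[risk²]·(E[L²]−1) ≈ 10⁻⁴ of the risk itself); the calibration test
uses paired ±3·SE comparisons, which comfortably contain this term at the
default panel dispersion.

## Screening policy

Strict inequalities throughout ("higher than"): referral > 6%; annual >
1.16% on the closed-open age band [40, 45) and > 1.19% otherwise; then the
biennial (> 0.80%) and triennial (> 0.40%) bands; otherwise watch-and-wait,
replaced by triennial at age ≥ 50 because women that age are already invited
biennially by the population program. The biennial/triennial cut-offs are
placeholders bracketing the observed risk quartiles of those recommendation
groups; they are parameters of `ThresholdPolicy` and should be set from the
deployment's own protocol.

## Synthetic cohort

The generator emulates the study population, not any real registry: ages on
[40, 50) from 40 + 10·Beta(5, 1.3) (left-skewed, median ≈ 48.3, echoing the
trial's median 48.4); density a/b/c/d at 14.7/30.7/44.6/10.0%; family
history 9.8%; benign lesions none/non-proliferative/unspecified at
86.1/5.9/8.0%; density missing completely at random at 1.6% (women excluded
from estimation and reported, mirroring the trial's 372/387 estimable).
Genotypes are per-SNP Binomial(2, p) under HWE, independent across SNPs and
of the classical factors — by design matching the PRS model's assumptions,
so passing calibration tests validates the arithmetic, not the biological
assumptions. Survey responses are drawn i.i.d. from per-item Likert
marginals shaped like the trial's outcome tables, with 5%
missing-completely-at-random non-response per item.

The default example panel draws 83 SNP frequencies uniform on (0.10, 0.90)
and per-allele odds ratios uniform on (1.02, 1.20); for an 83-SNP panel
this yields a composite-likelihood-ratio spread (log-scale SD ≈ 0.6)
matching the interquartile range reported for the trial's PRS. A single
global seed is split into independent child streams (risk factors,
genotypes, survey) via numpy `SeedSequence.spawn`, so each stage is
separately reproducible and byte-identical across reruns.

What the generator does **not** emulate: correlation between risk factors,
population stratification or LD in genotypes, informative non-response, and
the joint distribution of PRS with classical factors. Cohort-level numbers
computed on synthetic data (recommendation mix, reclassification fraction)
therefore characterize the method under its own assumptions, not the trial
population.

## Numerical and design choices

- Risks are fractions everywhere internally; percentages appear only at
  output boundaries (result CSVs, reports, thresholds expressed in percent
  inside `ThresholdPolicy`). This avoids double-percent bugs at cut-offs
  like 1.16%.
- Table percentages round half-away-from-zero to one decimal; pictogram
  counts round to the nearest integer out of 1000.
- Clopper–Pearson intervals invert exact binomial tails (via
  `scipy.stats.binomtest`); the sample-size rule uses the two-sided normal
  quantile (1.959964 at 95%), giving n = 385 for a 5-point half-width at
  p = 0.5.
- No imputation anywhere: missing density excludes a woman from risk
  estimation (reported in a skip list); missing survey items shrink the
  block's denominator, which is always reported.
- Problem sizes: the cohort-level calibration and reclassification checks
  use 20,000 simulated women — large enough that Monte-Carlo error (±3 SE)
  separates real miscalibration from noise at the 10⁻⁴ risk scale, small
  enough to run in seconds.
- Degenerate inputs: zero incidence gives zero risk; a prior of exactly 1
  is rejected (odds undefined); an all-reference profile has rr = 1; an
  empty panel and empty survey blocks are structured errors, not NaNs.

## Known limitations

Hazards beyond age 70 are a flat extrapolation; coefficients and hazards are
stand-ins pending registry/published inputs; factor independence and
SNP-classical independence are assumed rather than estimated; the PRS odds
update ignores the (tiny) within-horizon hazard/odds distinction; no 10-year
or lifetime horizons.
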
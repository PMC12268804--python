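# Methods

## The probit tolerance model

Every analysis in this package rests on the classical quantal-response
model: each insect carries a log-normal tolerance, so the probability of
dying at concentration *c* (μg a.i./mL) is

    P(death) = Φ(α + β · log₁₀ c)

with Φ the standard normal CDF. α (probits) and β (probits per log₁₀
μg/mL, the "slope") are estimated by maximum likelihood — a binomial GLM
with probit link, fitted by iteratively reweighted least squares
(statsmodels, deviance tolerance 1e-8, 100 iterations). The parameter
covariance is the IRLS (expected-information) covariance, the same matrix
R's `glm`/`vcov` produces and `MASS::dose.p` consumes, so LC_p standard
errors match the standard R workflow for these assays. Control rows
(concentration 0) never enter the likelihood; Abbott's correction
(obs − c)/(1 − c) is available but off by default, with assays rejected
outright at ≥ 20% control mortality.

Degenerate data are refused rather than mangled: fewer than two distinct
positive concentrations, identical mortality in every group
(unidentifiable slope), or a perfect 0 → 100% step (complete separation:
the MLE diverges) each raise a specific error.

**LC_p and its CI.** log₁₀LC_p = (Φ⁻¹(p) − α)/β; the delta-method
variance uses the gradient (−1/β, −log₁₀LC_p/β) and the CI is
10^(log₁₀LC_p ± 1.96·se). Fieller/fiducial limits are deliberately not
implemented (delta-method matches the `dose.p` convention; for the
well-conditioned fits these assays produce the two nearly coincide).

**Goodness of fit and heterogeneity.** Pearson χ² over concentration
groups (replicates pooled per concentration first), df = groups − 2. When
its p-value is below 0.05 the heterogeneity factor χ²/df multiplies
delta-method variances downstream — the classic correction for
overdispersed assays. Reported slope/SE values are not inflated, matching
how published tables print them.

**Resistance ratios.** RR = LC_p(R)/LC_p(S); treating the two fits as
independent, se(log₁₀RR) = √(se_R² + se_S²) and the CI is
RR·10^(±1.96·se). Ratios built from published point values (no SEs) are
flagged `inputs_rounded` — quotients of rounded LC₅₀s can differ in the
last printed digit from ratios computed on unrounded internal values, so
reports must distinguish the two.

**Equality and parallelism.** Likelihood-ratio χ² between separate lines
and a constrained model: one common line (equality, df = 2(L−1)) or
common slope with free intercepts (parallelism, df = L−1). For reciprocal
F1 crosses, non-rejection of both is the standard evidence for autosomal,
non-maternal inheritance. The statistic is invariant to concentration
rescaling, which only shifts intercepts.

**Diagnostic dose.** The upper 95% limit of the susceptible strain's LC₉₉
— a discriminating concentration at which susceptible survivors are rare,
used to track resistance frequency over generations.

## Dominance statistics

Stone's D = (2X_F − X_R − X_S)/(X_R − X_S) on log₁₀ LC₅₀s summarises
dominance on the tolerance scale (+1 dominant, −1 recessive); it is
computed from unrounded LC₅₀s whenever fits are supplied and rounded only
for display. Bourguet's D = (M_RS − M_SS)/(M_RR − M_SS) on mortalities is
dose-specific; evaluated along a concentration grid from three fitted
lines it yields the DML curve, which declines as dose rises whenever the
heterozygote line sits between the parents. Values outside [−1, 1] —
possible under non-monotone observed mortalities — are returned with an
`out_of_range` flag, never clamped. Classification uses a ±0.005 band
around ±1 for the "complete" labels; D = 0 is labelled as the additive
midpoint.

Functional dominance at field rates uses pairwise two-proportion z-tests
with a single-step max-|z| (Tukey-type, studentized range with infinite
df) familywise adjustment, falling back to a Fisher mid-p with Šidák
adjustment when any cell count is below 5, plus an insert-absorb compact
letter display. A deviance-based GLM comparison would be the main
alternative; the proportion-test route was chosen because it yields the
per-pair adjusted p-values and letters directly on the scale the counts
live on.

## The backcross monogenic test

Under one-locus control, a backcross of F1 heterozygotes to the
susceptible parent segregates 1:1, so expected mortality at concentration
*i* is p = (a + b)/2 with a, b the heterozygous and susceptible parent
mortalities there. The test statistic per concentration is
χ² = (Nᵢ − p·nᵢ)²/(p·(1−p)·nᵢ), df = 1 — algebraically the squared
one-sample proportion z. Row-wise significance is reported at α = 0.05
with no multiplicity adjustment (mirroring how such tables are
published); the experiment-wise verdict "rejected if any row is
significant" is an explicit, configurable policy (`any-row`, default, or
`bonferroni`). Under the any-row policy the false-rejection rate of a
six-concentration screen is ≈ 1 − 0.95⁶ ≈ 26%, which the power study
reproduces; this is a property of the published presentation, not a bug.

The χ² assumes the expectation p is known. In the analysis of real data,
parental mortalities come from the observed counts at the same tested
concentration when available, else from the parental probit fits (the
source is recorded per row). In the Monte-Carlo calibration and power
studies the exact generating-model mortalities are used, keeping the
per-row type-I error at its nominal level; plugging in noisy observed
parental mortalities would inflate it.

## The simulator

`GeneticArchitecture` places log₁₀ tolerance additively over k unlinked
loci: baseline X_S, all-R endpoint X_R, per-locus effect
(X_R − X_S)/(2k) per R allele by default, heterozygous loci contributing
2·h·effect. With equal effects the all-heterozygous F1 has Stone's
D = 2h − 1 for any k, so emulating a study strain set parameterises h from
the published D ((D+1)/2) rather than from an unobservable per-locus h;
polygenic alternatives keep the same endpoints, isolating the effect of
locus number. A common probit slope across genotypes is the default
(published per-strain slopes are similar); per-genotype slopes would be a
straightforward extension.

Defaults mirror the study conditions: parental LC₅₀s 0.64 and 3,080.95
μg/mL, slopes 1.5–1.88, F1 at D = 0.13, 40 insects per concentration,
backcross screens at 3.2–560 μg/mL (six log-spaced doses), diagnostic
dose 100 μg/mL, six-generation cages, census 600 (the rearing-cage scale),
480 insects screened per generation (60 replicates × 8).

Crosses enumerate the exact offspring distribution (products of per-locus
Mendelian distributions, k ≤ 10) alongside sampling. Bioassay simulation
draws genotype counts multinomially, then deaths binomially per genotype.
Cage dynamics are discrete, non-overlapping generations: viability
selection (fitness 1−s for RR, 1−h_c·s for RS, 1 for SS) on the current
genotype frequencies, random mating to Hardy-Weinberg proportions of the
post-selection allele frequency, then (stochastic mode) multinomial
resampling of the census. Founding cages contain only RR and SS adults,
so generation 1 applies selection to that non-HWE mixture; from
generation 1 onward the allele frequency follows the textbook one-locus
recursion p' = p(1 − s(p + h_c q))/(1 − s(p² + 2h_c pq)). With s = 0 the
stochastic allele frequency is a martingale — the basis of one of the
acceptance checks. `selection_response` adds per-generation insecticide
exposure as an extra viability factor and reports the population's
effective LC₅₀ (root of the mixture mortality curve at 50%) and its RR,
reproducing qualitatively the monotone rise of RR under selection and its
decay under a fitness cost without exposure.

What the simulator does not emulate: overlapping generations, migration,
mutation, linkage, mating structure, sex linkage (reciprocal labels are
metadata; the architectures are autosomal), density dependence, and any
behavioural component of exposure. Passing tests therefore validate the
statistical machinery under the model's own assumptions, not the field
biology of any particular population; published field trajectories
depend on the real population's unknown architecture and are only
reproduced qualitatively (monotone trends), never numerically.

## Numerical choices and edge cases

- Grid-search oracle (tests only): the fitted log-likelihood is checked
  against an independent zoomed dense grid over (log₁₀LC₅₀, β) to 1e-3.
- LC_p at p = 0.5 reduces to 10^(−α/β) exactly; a unit test holds this to
  machine precision.
- Abbott-corrected counts are rounded to integers and clamped to
  [0, n]; correction provenance is attached to the table.
- Duplicate concentrations are pooled before Pearson grouping.
- Stability monitoring tables with a missing generation are flagged, not
  interpolated; single-treatment or single-generation inputs degrade to
  reporting without comparisons.
- All simulators take explicit integer seeds (numpy `default_rng`;
  experiment-level functions spawn child streams per strain), and equal
  seeds give byte-identical CSV output.

## Known limitations

- Only the probit link on log₁₀ dose; no logit/cloglog, no time-to-death
  models, no mixed-effects overdispersion modelling beyond the
  heterogeneity factor.
- The monogenic χ² treats expectations as known; parental sampling error
  is not propagated (consistent with the test's standard published form).
- The fitness-cost model is a bare viability coefficient; the magnitude
  of real costs cannot be identified from a single decay trajectory
  (s and h_c trade off), so calibration is left to the user.
- Letter displays use large-sample pairwise tests; with many treatments
  and tiny counts the Šidák fallback is conservative.
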
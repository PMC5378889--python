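# Methods

## Model and estimands

For a biallelic variant coded by minor-allele count g ∈ {0, 1, 2}, let Y_i
denote the trait in genotype group i, with group 0 the reference.  The
estimands are the nonparametric risks

    f_1 = Pr(Y_0 < Y_1),   f_2 = Pr(Y_0 < Y_2),   f_12 = Pr(Y_1 < Y_2)

and the nonparametric odds λ_i = f_i/(1 − f_i).  Under no association
f_i = 1/2 and λ_i = 1; the ordered alternative is λ_2 ≥ λ_1 ≥ 1 with
λ_2 > 1.  Genetic models are expressed on the same scale:

- recessive — f_2R = Pr(Y_{0∪1} < Y_2): only two minor alleles matter;
- dominant — f_1D = Pr(Y_0 < Y_{1∪2}): one copy is as good as two;
- additive — λ_1 = λ_12 (a graded effect); the single summary is
  f_1A = w_1 f̂_1 + w_12 f̂_12 with sample-size-proportion weights
  w_1 = (n_0+n_1)/(n_0+2n_1+n_2), w_12 = (n_1+n_2)/(n_0+2n_1+n_2)
  (group 1 is counted in both pairwise estimates, hence the denominator).

These are functionals of the two distributions only, so every statistic in
the package is invariant under strictly increasing transformations of the
trait — the point of the method for non-normal traits.

## Estimation

f̂ is the proportion of cross-group pairs won by the comparison group, ties
counted 1/2 — the normalized Mann–Whitney U with midranks, computed in
O(n log n) by sorting and verified in the tests against the O(n²) double
loop.  Variances use placements: P_j, the fraction of the comparison group
beaten by reference observation j, and Q_k, the fraction of the reference
group beaten by comparison observation k; then

    Var(f̂) ≈ s²_P / n_ref + s²_Q / n_cmp

with unbiased (n−1) sample variances (the Brunner–Munzel/DeLong form).
Covariances between two estimates sharing a group are sample covariances of
the shared group's placement vectors divided by the shared size; the
shared-middle covariance of (f̂_1, f̂_12) is negative, which is why the
additive combination gains little from inverse-variance reweighting.  When
f̂ = 1 (possible only in tiny groups) the odds estimator is undefined and
reported as +∞ with a warning, and infinite interval widths are excluded
from length averages with a counter.

The asymptotic contract — (f̂ − f)/se → N(0,1) as min group size grows —
is exercised empirically: Monte-Carlo tests check that the variance
estimator matches the sampling variance of f̂ within 10% and that implied
correlations match empirical correlations of paired estimates within three
Monte-Carlo standard errors.  Calibration is good from roughly a thousand
subjects; at n ≲ 600 with a rare homozygote group the weighted additive
test is mildly anti-conservative (rejection ≈ 0.06 at nominal 0.05).

## Confidence intervals

All three intervals are built on the f scale and mapped through the
strictly increasing f ↦ f/(1−f):

- **Standard**: f̂ ∓ z_{1−α/2}·se, clipped to [0,1] before mapping (the
  mapping is undefined outside; a flag records clipping).
- **Wilson**: f̂ is treated as a binomial proportion with effective sample
  size N = f̂(1−f̂)/Var(f̂) — the number of Bernoulli trials carrying the
  same information — and X = N·f̂ successes; the score interval follows.
  At f̂ ∈ {0,1} the effective N is undefined; the fallback borrows the
  smaller group size and clips X half a trial inward, flagged.
- **Log-Delta**: delta method on ζ = log λ, Var(ζ̂) = Var(f̂)/(f̂(1−f̂))²,
  bounds exp(ζ̂ ∓ z·sd).  Always positive, always contains λ̂.

Interval length is averaged on the λ scale, where the odds are reported.
Empirically Wilson ≤ Log-Delta ≤ Standard in mean length, and all three
cover near the nominal 95%.

## Tests

Z_model = (f̂_model − ½)/se(f̂_model) with the plug-in (unrestricted)
placement variance, two-sided p = 2(1 − Φ(|Z|)) by default; the ordered
one-sided alternative is available.  The group-size-only null variance
(n_ref+n_cmp+1)/(12 n_ref n_cmp) was evaluated as an alternative and
rejected: it costs power under shift alternatives without improving null
calibration.

**MAX3** = max(|Z_R|, |Z_A|, |Z_D|).  Under the null the three statistics
are jointly asymptotically normal with correlations (γ_RA, γ_AD, γ_RD)
induced by shared observations.  The correlations are estimated by a
plug-in Gram matrix of per-individual influence vectors (each effect's
placements, centred per genotype group and scaled by group size, with
n_g/(n_g−1) corrections), which is positive semi-definite by construction;
a nearest-PSD projection guards against numerical clipping and is flagged
if it ever fires.  The p-value is 1 − Pr(−m ≤ W ≤ m) for the fitted
trivariate normal.  This rectangle probability is evaluated
deterministically: conditioning on one coordinate reduces it to a 1-D
Gauss–Legendre integral (128 nodes) of bivariate-normal rectangles, with
the bivariate CDF computed from its arcsin-substitution integral (64
nodes) — smooth for all correlations including ±1.  Accuracy is below
1e-7 absolute (checked against scipy's QMC integrator and both closed-form
limits), at ~1 ms per call with no random stream.  A label-permutation
p-value is available as a cross-check.

Covariates are removed EIGENSTRAT-style: OLS residuals of the trait on an
intercept plus covariates become the outcome.  Residualization restores
nominal type-I error in a simulated confounder scenario.

## Comparators

Kruskal–Wallis and F tests delegate to scipy (two-group KW is the squared
standardized Wilcoxon; the additive F test is the regression slope test on
the 0/1/2 count).  Jonckheere–Terpstra is implemented here (scipy has
none): sum of pairwise Mann–Whitney counts over ordered groups,
standardized with the tie-corrected Hollander–Wolfe moments, normal
reference; with two groups it reduces exactly to the tie-corrected
Wilcoxon, and it is validated against a label-permutation oracle.

## Simulation engine

Genotypes are i.i.d. Binomial(2, MAF) (Hardy–Weinberg).  Traits follow
y = β₀ + β₁·x(g) + ε.  The genotype score x(g) is on the allele-count
scale for all three generating models — additive (0,1,2), recessive
(0,0,2), dominant (0,2,2) — so the homozygote contrast is always 2β₁; this
is what makes the recessive and dominant odds at β₁ = 0.25 equal the
additive genotype-1 odds at β₁ = 0.5 (both are the odds of a 0.5 shift,
1.97).

Errors are truncated GEV.  tGEV(ξ, μ, σ, c) is GEV(ξ, μ, σ) conditioned on
X ≥ c, sampled by inverse CDF on the conditional law (deterministic given
the uniform stream); truncation applies to the final located/scaled
variable, so the support is [c, ∞) whatever the scale.  The Gumbel branch
ξ = 0 is implemented explicitly.  Defaults follow the study conditions
throughout: β₀ = 0.5, tGEV(0,0,1,0) for estimation/type-I cells and
tGEV(0,0,5,0) for power cells, n = 1500, 2000 replicates, α = 0.05, with
MAF and β₁ per cell.  Standard-normal and centred-t errors are provided
for robustness checks.  These defaults emulate a truncated, heavy-tailed
antibody-like trait; they do not emulate linkage disequilibrium between
variants, genotyping error, missingness patterns or population structure,
so passing calibration here says nothing about confounding robustness
beyond the explicit residualization scenario.

The true odds per cell comes from the exact 1-D integral
f = ∫ F(d+u) dF(u) over the error law (adaptive quadrature, absolute error
< 1e-6), where d is the generating contrast for the effect in question —
never from simulation.  `run_cell` seeds each replicate from a spawned
SeedSequence child, so cells are reproducible and order-independent;
replicates with an empty genotype group (possible at low MAF) are redrawn
with a logged counter, since the estimators require all groups populated.

## Numerical and design notes

- z-quantiles from the exact normal inverse CDF; α = 0.05 throughout the
  replication cells.
- All placement computations share one sorted-search kernel; ties get
  weight 1/2 everywhere, including the JT statistic and the tie-corrected
  variances.
- The per-variant table never aborts: monomorphic or degenerate variants
  yield NA cells with a reason code.  Missing genotypes are dropped per
  variant (complete case); the minor allele is recounted per variant so
  genotype 2 always counts the rarer allele.
- Known limitations: biallelic variants only; prospective-sampling
  interpretation of the odds (in case-control sampling the tests remain
  valid but λ̂ estimates the odds in the sampled mixture); asymptotic
  p-values only (the permutation option exists for MAX3); no
  exact small-sample intervals.
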
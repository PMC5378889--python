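# npodds — nonparametric risk and odds for quantitative-trait association

Many quantitative traits in genetic association studies are not even
approximately normal — antibody titres, for instance, are heavy-tailed and
truncated at an assay floor, and no transformation fixes both problems at
once.  A linear-regression coefficient is then a poor effect size, and the
usual rank tests (Kruskal–Wallis, Jonckheere–Terpstra) give p-values but no
interpretable measure of genetic effect.

`npodds` implements a rank-based effect size for a biallelic variant
against a continuous trait.  With genotype 0 (no minor alleles) as the
reference group, the **nonparametric risk** of genotype group *i* is

    f_i = Pr(Y_0 < Y_i),        i = 1, 2

the probability that a trait value drawn from group *i* exceeds one drawn
from the reference group, and the **nonparametric odds** is

    λ_i = f_i / (1 − f_i)

which equals 1 under no association, mirroring how an odds ratio behaves
for binary traits.  The package provides:

- placement (Mann–Whitney/Brunner–Munzel-type) point estimates of
  f₁, f₂, f₁₂ and of the genetic-model effects f₂ᴿ (recessive: genotype 2
  vs pooled 0∪1), f₁ᴰ (dominant: carriers vs genotype 0) and f₁ᴬ
  (additive: a sample-size-weighted combination of f̂₁ and f̂₁₂),
  with variance and covariance estimators built from placements;
- three confidence intervals on the odds scale — **Standard** (Wald),
  **Wilson** (effective-sample-size score interval) and **Log-Delta**
  (delta method on log λ);
- model-specific tests Z_R, Z_A, Z_D ((f̂ − ½)/se, asymptotically normal)
  and the robust **MAX3** = max(|Z_R|, |Z_A|, |Z_D|), whose p-value comes
  from the trivariate-normal null with estimated correlations;
- comparator tests (Kruskal–Wallis, F/ANOVA and regression slope,
  Jonckheere–Terpstra) under the same genetic-model groupings;
- a simulation engine (HWE genotypes, linear trait model with
  truncated-Gumbel, normal or centred-t errors) that reproduces the
  calibration metrics — bias, sMSE, coverage, interval length, type-I
  error, power;
- VCF/TSV input and a CLI (`npodds assoc|simulate|ci`) for per-variant
  analysis with optional covariate residualization and Bonferroni
  correction.

## Worked example

Simulate one variant at minor allele frequency 0.30 under the additive
linear model y = 0.5 + 0.5·g + ε with truncated-Gumbel errors, and fit:

```python
import numpy as np
from npodds import NonparametricOdds, SimConfig, gen_genotypes, gen_trait

rng = np.random.default_rng(1)
cfg = SimConfig(maf=0.3, beta1=0.5, n=2000, seed=1)
g = gen_genotypes(cfg.n, cfg.maf, rng)
y = gen_trait(g, cfg, rng)

res = NonparametricOdds(y, g).fit(ci_method="wilson")
print(res.summary())
```

```
        Nonparametric Odds Association Results
==============================================================
No. observations:     2000    genotype groups (n0/n1/n2): 987/825/188
CI method:         wilson    level: 95%
--------------------------------------------------------------
effect    f_hat   lambda    se(f)   [ci low  ci high]
f1       0.6583    1.926   0.0126     1.726     2.150
f2       0.7654    3.262   0.0143     2.791     3.813
f12      0.6486    1.846   0.0190     1.567     2.174
f2R      0.7122    2.475   0.0147     2.152     2.847
f1A      0.6548    1.897   0.0087     1.759     2.046
f1D      0.6782    2.107   0.0120     1.891     2.347
--------------------------------------------------------------
test        statistic    p-value
recessive     14.4778  1.673e-47
additive      17.7310  2.417e-70
dominant      14.8116  1.234e-49
max3          17.7310  6.439e-15
==============================================================
```

Read: a heterozygote's trait value beats a reference subject's 65.8% of
the time (λ̂₁ = 1.93, CI 1.73–2.15, excluding 1); the homozygote odds
λ̂₂ = 3.26 is roughly λ̂₁², as an additive model predicts (the generating
truth is λ₁ = 1.97, λ₂ = 3.58).  All three model tests and MAX3 reject
decisively.  (The MAX3 p-value is bounded below by the trivariate-normal
integration accuracy and is best read as p < 1e-10 here.)

The same analysis runs from the shell on a VCF plus a phenotype TSV:

```bash
npodds assoc --genotypes study.vcf --phenotype trait.tsv \
       --ci-method wilson --model all --out results.tsv
```

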
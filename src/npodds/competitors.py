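"""Reference tests: Kruskal-Wallis, F, and Jonckheere-Terpstra.

These are the standard alternatives a practitioner would run, each applied
under the three genetic-model groupings of the genotype:

    recessive : {0 or 1} vs {2}
    dominant  : {0} vs {1 or 2}
    additive  : {0} < {1} < {2} (ordered; the F test becomes the regression
                slope test on the 0/1/2 allele count)

Kruskal-Wallis and the F/ANOVA tests delegate to scipy.  Jonckheere-Terpstra
is implemented here (scipy has none): the statistic is the sum of pairwise
Mann-Whitney counts over ordered group pairs, standardized with the
tie-corrected null mean and variance and referred to the normal
distribution — the large-sample behaviour of R's ``jonckheere.test``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .association import TestResult
from .effects import EstimationError, GroupedSample

__all__ = ["competitor_test", "jonckheere_terpstra", "COMPETITORS"]

COMPETITORS = ("KW", "F", "JT")


def _model_groups(sample: GroupedSample, model: str):
    if model == "recessive":
        groups = [np.concatenate([sample.y0, sample.y1]), sample.y2]
    elif model == "dominant":
        groups = [sample.y0, np.concatenate([sample.y1, sample.y2])]
    elif model == "additive":
        groups = [sample.y0, sample.y1, sample.y2]
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    groups = [g for g in groups]
    if sum(g.size > 0 for g in groups) < 2 or any(g.size == 0 for g in groups):
        raise EstimationError(f"{model} grouping leaves an empty group")
    return groups


def jonckheere_terpstra(groups, alternative: str = "two-sided") -> TestResult:
    """Jonckheere-Terpstra trend test for ordered groups, normal approximation.

    JT = sum over ordered pairs (a < b) of #{(x in a, y in b): x < y} with
    ties counted 1/2.  Mean and tie-corrected variance follow Hollander &
    Wolfe; with two groups this reduces to the (tie-corrected) Wilcoxon
    rank-sum.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size == 0 for g in groups):
        raise EstimationError("empty group in Jonckheere-Terpstra test")
    ns = np.array([g.size for g in groups], dtype=float)
    pooled = np.concatenate(groups)
    n = pooled.size

    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            bs = np.sort(b)
            lo = np.searchsorted(bs, a, side="left")
            hi = np.searchsorted(bs, a, side="right")
            jt += float(np.sum(b.size - 0.5 * (lo + hi)))

    mean = (n * n - np.sum(ns ** 2)) / 4.0
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    var = (
        (n * (n - 1) * (2 * n + 5)
         - np.sum(ns * (ns - 1) * (2 * ns + 5))
         - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
        + np.sum(ns * (ns - 1) * (ns - 2)) * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * n * (n - 1) * (n - 2))
        + np.sum(ns * (ns - 1)) * np.sum(t * (t - 1)) / (8.0 * n * (n - 1))
    )
    if var <= 1e-10:
        raise EstimationError("degenerate Jonckheere-Terpstra variance (all values tied)")
    z = (jt - mean) / math.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(stats.norm.sf(z))
    else:
        p = float(stats.norm.cdf(z))
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), model="jt")


def competitor_test(sample: GroupedSample, which: str, model: str) -> TestResult:
    """Run one reference test under one genetic-model grouping."""
    which = which.upper()
    if which == "KW":
        groups = _model_groups(sample, model)
        stat, p = stats.kruskal(*groups)
        return TestResult(statistic=float(stat), p_value=float(p),
                          model=f"KW-{model[0].upper()}")
    if which == "F":
        if model == "additive":
            # regression slope test of trait on allele count (1-df F = t^2)
            g = np.concatenate([np.zeros(sample.n0), np.ones(sample.n1),
                                np.full(sample.n2, 2.0)])
            y = np.concatenate(sample.groups())
            if sample.n0 == sample.n or sample.n2 + sample.n1 == 0:
                raise EstimationError("additive F test needs genotype variation")
            res = stats.linregress(g, y)
            t = res.slope / res.stderr if res.stderr > 0 else math.inf
            return TestResult(statistic=float(t * t), p_value=float(res.pvalue), model="F-A")
        groups = _model_groups(sample, model)
        stat, p = stats.f_oneway(*groups)
        return TestResult(statistic=float(stat), p_value=float(p),
                          model=f"F-{model[0].upper()}")
    if which == "JT":
        groups = _model_groups(sample, model)
        res = jonckheere_terpstra(groups)
        return TestResult(statistic=res.statistic, p_value=res.p_value,
                          model=f"JT-{model[0].upper()}")
    raise ValueError(f"unknown competitor {which!r}; choose from {COMPETITORS}")
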
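"""Model / Results interface for a single-variant nonparametric odds analysis.

``NonparametricOdds`` holds a trait, a 0/1/2 genotype vector and optional
covariates; ``fit`` residualizes the trait if covariates are present,
estimates the pairwise and model-specific nonparametric odds with their
confidence intervals, runs the three model tests and MAX3, and returns a
``NonparametricOddsResults`` with a statsmodels-flavoured ``summary()``.

    >>> model = NonparametricOdds(trait, genotypes)
    >>> res = model.fit(ci_method="wilson")
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import TestResult, residualize, z_test
from .effects import (EstimationError, GroupedSample, estimate_f, model_effect)
from .intervals import CI_METHODS, ConfidenceInterval, interval
from .max3 import max3_test, null_correlations

__all__ = ["NonparametricOdds", "NonparametricOddsResults"]


class NonparametricOdds:
    """Nonparametric risk/odds model for one biallelic variant.

    Parameters
    ----------
    endog : array-like
        Continuous trait values.
    genotypes : array-like of {0, 1, 2}
        Minor-allele counts per subject (genotype 0 is the reference group).
    covariates : array-like or DataFrame, optional
        Confounders; the trait is replaced by its OLS residuals on them
        before any rank comparison.
    """

    def __init__(self, endog, genotypes, covariates=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.genotypes = np.asarray(genotypes).ravel()
        if self.endog.size != self.genotypes.size:
            raise ValueError("endog and genotypes must have equal length")
        self.covariates = covariates
        outcome = (residualize(self.endog, covariates)
                   if covariates is not None else self.endog)
        self.sample = GroupedSample.from_genotypes(outcome, self.genotypes)

    @classmethod
    def from_dataframe(cls, data, trait: str, genotype: str, covariates=None):
        cov = data[list(covariates)] if covariates else None
        return cls(data[trait].to_numpy(), data[genotype].to_numpy(), cov)

    def fit(self, alpha: float = 0.05, ci_method: str = "wilson") -> "NonparametricOddsResults":
        if ci_method not in CI_METHODS:
            raise ValueError(f"ci_method must be one of {CI_METHODS}")
        s = self.sample
        effects, conf_ints, tests = {}, {}, {}
        specs = [
            ("f1", lambda: estimate_f(s.y0, s.y1, label="f1")),
            ("f2", lambda: estimate_f(s.y0, s.y2, label="f2")),
            ("f12", lambda: estimate_f(s.y1, s.y2, label="f12")),
            ("f2R", lambda: model_effect(s, "recessive")),
            ("f1A", lambda: model_effect(s, "additive")),
            ("f1D", lambda: model_effect(s, "dominant")),
        ]
        for label, fn in specs:
            try:
                est = fn()
                effects[label] = est
                if est.var_f > 0 and np.isfinite(est.var_f):
                    conf_ints[label] = interval(est, alpha, method=ci_method)
            except EstimationError:
                continue
        for model in ("recessive", "additive", "dominant"):
            try:
                tests[model] = z_test(s, model)
            except EstimationError:
                continue
        if len(tests) == 3:
            try:
                tests["max3"] = max3_test(s)
            except EstimationError:
                pass
        return NonparametricOddsResults(self, alpha, ci_method, effects, conf_ints, tests)


@dataclass
class NonparametricOddsResults:
    """Fit results: effect estimates, odds-scale intervals and tests."""

    model: NonparametricOdds
    alpha: float
    ci_method: str
    effects: dict
    conf_ints: dict
    tests: dict

    @property
    def sample(self) -> GroupedSample:
        return self.model.sample

    def conf_int(self, label: str = "f1") -> ConfidenceInterval:
        return self.conf_ints[label]

    def test(self, model: str) -> TestResult:
        return self.tests[model]

    @property
    def pvalues(self) -> dict:
        return {k: t.p_value for k, t in self.tests.items()}

    def null_correlations(self):
        return null_correlations(self.sample)

    def summary(self) -> str:
        s = self.sample
        lines = []
        lines.append("        Nonparametric Odds Association Results")
        lines.append("=" * 62)
        lines.append(f"No. observations: {s.n:>8}    genotype groups "
                     f"(n0/n1/n2): {s.n0}/{s.n1}/{s.n2}")
        lines.append(f"CI method: {self.ci_method:>14}    level: {1 - self.alpha:.0%}")
        lines.append("-" * 62)
        lines.append(f"{'effect':<6} {'f_hat':>8} {'lambda':>8} "
                     f"{'se(f)':>8} {'[ci low':>9} {'ci high]':>9}")
        for label, est in self.effects.items():
            ci = self.conf_ints.get(label)
            lo = f"{ci.lower:9.3f}" if ci else "      ---"
            hi = f"{ci.upper:9.3f}" if ci else "     ---"
            se = np.sqrt(est.var_f) if est.var_f > 0 else np.nan
            lam = est.lambda_hat
            lam_s = f"{lam:8.3f}" if np.isfinite(lam) else "     inf"
            lines.append(f"{label:<6} {est.f_hat:8.4f} {lam_s} {se:8.4f} {lo} {hi}")
        lines.append("-" * 62)
        lines.append(f"{'test':<10} {'statistic':>10} {'p-value':>10}")
        for name, t in self.tests.items():
            lines.append(f"{name:<10} {t.statistic:10.4f} {t.p_value:10.4g}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def __repr__(self):
        k = ", ".join(self.effects)
        return f"<NonparametricOddsResults: effects [{k}], tests {list(self.tests)}>"
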
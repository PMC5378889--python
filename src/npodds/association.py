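"""Model-specific association tests and covariate adjustment.

Each genetic model (recessive / additive / dominant) defines one
nonparametric risk; the test standardizes it against the no-association
value 1/2:

    Z_model = (f_hat_model - 1/2) / sqrt(var_hat_model)

which is asymptotically standard normal when genotype and trait are
independent.  Two-sided p-values are the default; the ordered alternative
(trait stochastically increasing with minor-allele count) is available as
``alternative='greater'``.

Covariates are handled EIGENSTRAT-style: regress the trait on them by OLS
and use the residuals as the new outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effects import EffectEstimate, GroupedSample, model_effect, EstimationError


__all__ = ["TestResult", "z_test", "residualize"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    model: str
    effect: EffectEstimate | None = None
    method: str = "asymptotic"

    def __repr__(self):
        return (f"TestResult(model={self.model!r}, statistic={self.statistic:.4f}, "
                f"p_value={self.p_value:.4g})")


def z_test(sample: GroupedSample, model: str, alternative: str = "two-sided") -> TestResult:
    """Placement-based Z test of no association under one genetic model."""
    est = model_effect(sample, model)
    if not est.var_f > 0 or not np.isfinite(est.var_f):
        raise EstimationError(f"degenerate variance for the {model} test")
    z = (est.f_hat - 0.5) / math.sqrt(est.var_f)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), model=model, effect=est)


def residualize(trait, covariates=None) -> np.ndarray:
    """OLS residuals of the trait on an intercept plus covariates.

    With no covariates this is simple mean-centering.  Rank-deficient
    covariate matrices are rejected, naming the first redundant column.
    """
    trait = np.asarray(trait, dtype=float).ravel()
    if covariates is None or (hasattr(covariates, "size") and np.asarray(covariates).size == 0):
        return trait - trait.mean()
    import pandas as pd

    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{j}" for j in range(x.shape[1])]
    if x.shape[0] != trait.size:
        raise ValueError("covariate rows must match trait length")
    design = np.column_stack([np.ones(trait.size), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # find the first column that adds no rank
        r = 1
        for j in range(x.shape[1]):
            sub = design[:, : 2 + j]
            r_new = np.linalg.matrix_rank(sub)
            if r_new == r:
                raise ValueError(f"covariate {names[j]!r} is collinear with the others")
            r = r_new
        raise ValueError("covariate matrix is rank deficient")
    import statsmodels.api as sm

    res = sm.OLS(trait, design).fit()
    resid = np.asarray(res.resid, dtype=float)
    return resid - resid.mean()  # exact zero mean despite float round-off
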
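"""Confidence intervals for the nonparametric odds.

Three constructions, all built on the asymptotic normality of the estimated
risk f_hat and mapped to the odds scale through the strictly increasing
f -> f/(1-f):

Standard  : Wald bounds f_hat -/+ z*sqrt(var), clipped to [0,1] before mapping.
Wilson    : treat f_hat as a binomial proportion with effective sample size
            N = f_hat(1-f_hat)/var (the number of Bernoulli trials that would
            give the same variance) and X = N*f_hat successes, then apply the
            Wilson score interval.
Log-Delta : delta method on zeta = log lambda; Var(zeta_hat) =
            var / (f_hat(1-f_hat))^2; bounds exp(zeta_hat -/+ z*sd).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effects import EffectEstimate


__all__ = [
    "ConfidenceInterval",
    "standard_interval",
    "wilson_interval",
    "log_delta_interval",
    "interval",
    "CI_METHODS",
]

CI_METHODS = ("standard", "wilson", "log_delta")


def _lam(f: float) -> float:
    if f >= 1.0:
        return math.inf
    return f / (1.0 - f)


@dataclass(frozen=True)
class ConfidenceInterval:
    """Lower/upper bounds on the odds scale (with the f-scale bounds kept)."""

    lower: float
    upper: float
    level: float
    method: str
    scale: str = "lambda"
    f_lower: float = np.nan
    f_upper: float = np.nan
    clipped: bool = False
    degenerate: bool = False

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def length(self) -> float:
        return self.upper - self.lower


def _check(est: EffectEstimate, alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return stats.norm.ppf(1.0 - alpha / 2.0)


def standard_interval(est: EffectEstimate, alpha: float = 0.05) -> ConfidenceInterval:
    z = _check(est, alpha)
    if not est.var_f > 0:
        warnings.warn("zero variance: standard interval degenerates to the point estimate",
                      RuntimeWarning, stacklevel=2)
        lam = _lam(est.f_hat)
        return ConfidenceInterval(lam, lam, 1 - alpha, "standard",
                                  f_lower=est.f_hat, f_upper=est.f_hat, degenerate=True)
    half = z * math.sqrt(est.var_f)
    raw_lo, raw_hi = est.f_hat - half, est.f_hat + half
    f_lo, f_hi = max(raw_lo, 0.0), min(raw_hi, 1.0)
    clipped = (f_lo != raw_lo) or (f_hi != raw_hi)
    return ConfidenceInterval(_lam(f_lo), _lam(f_hi), 1 - alpha, "standard",
                              f_lower=f_lo, f_upper=f_hi, clipped=clipped)


def wilson_interval(est: EffectEstimate, alpha: float = 0.05) -> ConfidenceInterval:
    z = _check(est, alpha)
    if not est.var_f > 0:
        warnings.warn("zero variance: wilson interval degenerates to the point estimate",
                      RuntimeWarning, stacklevel=2)
        lam = _lam(est.f_hat)
        return ConfidenceInterval(lam, lam, 1 - alpha, "wilson",
                                  f_lower=est.f_hat, f_upper=est.f_hat, degenerate=True)
    f = est.f_hat
    fallback = not (0.0 < f < 1.0)
    if fallback:
        # no information about the effective N at the boundary; borrow the
        # smaller group size and clip the success count half a trial inward
        n_eff = float(min(est.n_ref, est.n_cmp))
    else:
        n_eff = f * (1.0 - f) / est.var_f
    x = min(max(n_eff * f, 0.5), n_eff - 0.5) if fallback else n_eff * f
    z2 = z * z
    denom = n_eff + z2
    center = (x + z2 / 2.0) / denom
    half = z * math.sqrt(x * (n_eff - x) / n_eff + z2 / 4.0) / denom
    f_lo, f_hi = center - half, center + half
    return ConfidenceInterval(_lam(f_lo), _lam(f_hi), 1 - alpha, "wilson",
                              f_lower=f_lo, f_upper=f_hi, degenerate=fallback)


def log_delta_interval(est: EffectEstimate, alpha: float = 0.05) -> ConfidenceInterval:
    z = _check(est, alpha)
    if not est.var_f > 0:
        warnings.warn("zero variance: log-delta interval degenerates to the point estimate",
                      RuntimeWarning, stacklevel=2)
        lam = _lam(est.f_hat)
        return ConfidenceInterval(lam, lam, 1 - alpha, "log_delta",
                                  f_lower=est.f_hat, f_upper=est.f_hat, degenerate=True)
    f = est.f_hat
    if not 0.0 < f < 1.0:
        warnings.warn("risk estimate at the boundary: log-delta interval undefined",
                      RuntimeWarning, stacklevel=2)
        lam = _lam(f)
        return ConfidenceInterval(0.0, math.inf, 1 - alpha, "log_delta",
                                  f_lower=f, f_upper=f, degenerate=True)
    zeta = math.log(f / (1.0 - f))
    sd_zeta = math.sqrt(est.var_f) / (f * (1.0 - f))
    lo = math.exp(zeta - z * sd_zeta)
    hi = math.exp(zeta + z * sd_zeta)
    return ConfidenceInterval(lo, hi, 1 - alpha, "log_delta",
                              f_lower=lo / (1 + lo), f_upper=hi / (1 + hi))


_DISPATCH = {
    "standard": standard_interval,
    "wilson": wilson_interval,
    "log_delta": log_delta_interval,
}


def interval(est: EffectEstimate, alpha: float = 0.05, method: str = "wilson") -> ConfidenceInterval:
    """Odds-scale confidence interval by name ('standard', 'wilson', 'log_delta')."""
    try:
        fn = _DISPATCH[method]
    except KeyError:
        raise ValueError(f"unknown interval method {method!r}; choose from {CI_METHODS}")
    return fn(est, alpha)
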
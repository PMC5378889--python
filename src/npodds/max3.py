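"""The MAX3 robust test.

The mode of inheritance is usually unknown; a test built for the wrong
genetic model can lose substantial power.  MAX3 takes the largest (in
absolute value) of the recessive, additive and dominant Z statistics.  Under
no association the vector (Z_R, Z_A, Z_D) is asymptotically trivariate
normal with mean zero, unit variances and correlations (gamma_RA, gamma_AD,
gamma_RD) induced by the shared observations, so the p-value is one minus a
trivariate-normal rectangle probability

    p = 1 - Pr(-m <= (W1, W2, W3) <= m),   m = max(|Z_R|, |Z_A|, |Z_D|).

Correlations are estimated by plugging in the placement influence vectors of
the three model effects (a Gram matrix, hence positive semi-definite by
construction).  The rectangle probability is computed deterministically by
conditioning on one coordinate: the trivariate rectangle becomes a 1-D
Gauss-Legendre integral of bivariate-normal rectangles, with the bivariate
CDF evaluated through its smooth arcsin-substitution integral.  Absolute
accuracy is well below 1e-5 and no random stream is involved.

A label-permutation p-value is available as ``method='permutation'``; it is
a check on the asymptotic approximation, not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import TestResult, z_test
from .effects import EstimationError, GroupedSample, effect_influence, influence_cov

__all__ = ["NullCorrelation", "null_correlations", "max3_test", "max3_pvalue"]

_MVN_SEED = 20150715  # for the scipy QMC fallback paths (signed variant)

# Gauss-Legendre nodes, cached: 64 points for the bivariate arcsin integral,
# 128 for the outer conditioning integral
_BVN_NODES = np.polynomial.legendre.leggauss(64)
_OUTER_NODES = np.polynomial.legendre.leggauss(128)


def _bvn_cdf(h, k, rho):
    """Bivariate standard normal CDF Pr(X <= h, Y <= k) with correlation rho.

    Uses Phi(h)Phi(k) + (1/2pi) * integral_0^{arcsin rho} of
    exp(-(h^2 + k^2 - 2 h k sin t) / (2 cos^2 t)) dt, which is smooth for
    all |rho| <= 1; vectorized over h, k.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(np.clip(rho, -1.0, 1.0))
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return base
    a = math.asin(rho)
    x, w = _BVN_NODES
    t = 0.5 * a * (x + 1.0)  # map [-1,1] -> [0, a]
    sin_t = np.sin(t)
    cos2_t = np.cos(t) ** 2
    hh = h[..., None]
    kk = k[..., None]
    expo = np.exp(-(hh ** 2 + kk ** 2 - 2.0 * hh * kk * sin_t) / (2.0 * cos2_t))
    integral = 0.5 * a * np.sum(w * expo, axis=-1)
    return base + integral / (2.0 * math.pi)


def _bvn_rectangle(lo2, hi2, lo3, hi3, rho):
    """Pr(lo2 <= X <= hi2, lo3 <= Y <= hi3) for standard bivariate normal."""
    return (_bvn_cdf(hi2, hi3, rho) - _bvn_cdf(lo2, hi3, rho)
            - _bvn_cdf(hi2, lo3, rho) + _bvn_cdf(lo2, lo3, rho))


def _tvn_symmetric_rectangle(m: float, corr: np.ndarray) -> float:
    """Pr(|W_i| <= m for i=1,2,3) for a centered trivariate normal.

    Conditions on W1: P = integral over w of phi(w) * bivariate rectangle of
    the conditional (W2, W3) | W1 = w, by Gauss-Legendre on [-m, m].
    """
    g12, g13, g23 = corr[0, 1], corr[0, 2], corr[1, 2]
    s2 = math.sqrt(max(1.0 - g12 ** 2, 0.0))
    s3 = math.sqrt(max(1.0 - g13 ** 2, 0.0))
    x, w = _OUTER_NODES
    u = m * x  # nodes on [-m, m]
    weights = m * w * stats.norm.pdf(u)
    # degenerate conditionals: W_i = +/- w exactly, always inside [-m, m]
    if s2 < 1e-8 and s3 < 1e-8:
        return float(np.sum(weights))
    if s2 < 1e-8 or s3 < 1e-8:
        g1i, si = (g13, s3) if s2 < 1e-8 else (g12, s2)
        lo = (-m - g1i * u) / si
        hi = (m - g1i * u) / si
        rect = stats.norm.cdf(hi) - stats.norm.cdf(lo)
        return float(np.sum(weights * rect))
    rho_c = np.clip((g23 - g12 * g13) / (s2 * s3), -1.0, 1.0)
    lo2, hi2 = (-m - g12 * u) / s2, (m - g12 * u) / s2
    lo3, hi3 = (-m - g13 * u) / s3, (m - g13 * u) / s3
    rect = _bvn_rectangle(lo2, hi2, lo3, hi3, rho_c)
    return float(np.sum(weights * np.clip(rect, 0.0, 1.0)))


@dataclass(frozen=True)
class NullCorrelation:
    gamma_RA: float
    gamma_AD: float
    gamma_RD: float
    projected: bool = False

    @property
    def matrix(self) -> np.ndarray:
        return np.array([
            [1.0, self.gamma_RA, self.gamma_RD],
            [self.gamma_RA, 1.0, self.gamma_AD],
            [self.gamma_RD, self.gamma_AD, 1.0],
        ])


def null_correlations(sample: GroupedSample) -> NullCorrelation:
    """Plug-in correlations of (Z_R, Z_A, Z_D) from placement influences."""
    if min(sample.n0, sample.n1, sample.n2) < 2:
        raise EstimationError("null correlations need >= 2 observations per genotype group")
    infl = {m: effect_influence(sample, m) for m in ("recessive", "additive", "dominant")}
    cov = np.empty((3, 3))
    order = ("recessive", "additive", "dominant")
    for i, a in enumerate(order):
        for j, b in enumerate(order[i:], start=i):
            cov[i, j] = cov[j, i] = influence_cov(infl[a], infl[b])
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise EstimationError("degenerate variance in null-correlation estimate")
    corr = cov / np.outer(d, d)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    projected = False
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        # nearest-PSD projection: clip eigenvalues, renormalize the diagonal
        vals, vecs = np.linalg.eigh(corr)
        corr = (vecs * np.maximum(vals, 0.0)) @ vecs.T
        d2 = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d2, d2)
        projected = True
    return NullCorrelation(
        gamma_RA=float(corr[0, 1]), gamma_AD=float(corr[1, 2]),
        gamma_RD=float(corr[0, 2]), projected=projected,
    )


def max3_pvalue(m: float, corr: NullCorrelation | np.ndarray, tol: float = 1e-6) -> float:
    """p = 1 - Pr(all three |W_i| <= m) under the correlated trivariate normal."""
    mat = corr.matrix if isinstance(corr, NullCorrelation) else np.asarray(corr, dtype=float)
    if m <= 0:
        return 1.0
    rect = _tvn_symmetric_rectangle(float(m), mat)
    return float(min(max(1.0 - rect, 0.0), 1.0))


def max3_test(
    sample: GroupedSample,
    method: str = "mvn",
    signed: bool = False,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> TestResult:
    """MAX3 robust association test.

    Parameters
    ----------
    method : 'mvn' (trivariate-normal p-value, default) or 'permutation'
        (label permutation of the trait against genotype).
    signed : use max(Z) instead of max(|Z|); one-sided for the ordered
        alternative. Default is the absolute-value version, matching the
        two-sided component tests.
    """
    zs = {m: z_test(sample, m) for m in ("recessive", "additive", "dominant")}
    stats_vec = np.array([zs[m].statistic for m in ("recessive", "additive", "dominant")])
    m_obs = float(np.max(stats_vec)) if signed else float(np.max(np.abs(stats_vec)))
    corr = null_correlations(sample)
    if method == "mvn":
        if signed:
            mvn = stats.multivariate_normal(
                mean=np.zeros(3), cov=corr.matrix, allow_singular=True, seed=_MVN_SEED,
            )
            p = float(1.0 - mvn.cdf(np.full(3, m_obs)))
        else:
            p = max3_pvalue(m_obs, corr)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        y = np.concatenate(sample.groups())
        n0, n1 = sample.n0, sample.n1
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(y)
            s = GroupedSample(perm[:n0], perm[n0:n0 + n1], perm[n0 + n1:])
            try:
                zp = [z_test(s, m).statistic for m in ("recessive", "additive", "dominant")]
            except EstimationError:
                continue
            mp = max(zp) if signed else max(abs(v) for v in zp)
            if mp >= m_obs:
                hits += 1
        p = (hits + 1.0) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=m_obs, p_value=p, model="max3", effect=None, method=method)
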
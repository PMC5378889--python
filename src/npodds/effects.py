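"""Placement-based estimation of nonparametric risk and odds.

The nonparametric risk of genotype group *i* against the reference group is
f_i = Pr(Y_ref < Y_i), estimated by the proportion of cross-group pairs in
which the comparison value wins (ties count 1/2) — the Mann-Whitney relative
effect.  The nonparametric odds is lambda_i = f_i / (1 - f_i); both equal
1/2 resp. 1 when genotype carries no information about the trait.

Variances and covariances use the placement (Brunner-Munzel / DeLong-type)
estimators: each observation's placement is the fraction of the *other*
group it beats, and the estimator variance is the sum of the two groups'
placement variances each divided by its group size.  Covariances between two
effects that share observations are the (co)variances of the shared group's
placement vectors, which is also how the MAX3 null correlations are built
(see :mod:`npodds.max3`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


__all__ = [
    "GroupedSample",
    "EffectEstimate",
    "PairCovariance",
    "placements",
    "estimate_f",
    "variance_f",
    "covariance_shared_ref",
    "covariance_shared_cmp",
    "model_effect",
    "effect_influence",
]

GENETIC_MODELS = ("recessive", "additive", "dominant")


class EstimationError(ValueError):
    """Raised when an effect is undefined for the given sample (empty group,
    degenerate variance)."""


@dataclass(frozen=True)
class GroupedSample:
    """Trait values partitioned by minor-allele count (genotype 0/1/2)."""

    y0: np.ndarray
    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self):
        for name in ("y0", "y1", "y2"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite trait values in {name}")
            object.__setattr__(self, name, arr)

    @classmethod
    def from_genotypes(cls, trait, genotypes) -> "GroupedSample":
        trait = np.asarray(trait, dtype=float).ravel()
        genotypes = np.asarray(genotypes).ravel()
        if trait.shape != genotypes.shape:
            raise ValueError("trait and genotypes must have equal length")
        if not np.isin(genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be coded 0/1/2")
        return cls(trait[genotypes == 0], trait[genotypes == 1], trait[genotypes == 2])

    @property
    def n0(self) -> int:
        return self.y0.size

    @property
    def n1(self) -> int:
        return self.y1.size

    @property
    def n2(self) -> int:
        return self.y2.size

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2

    def groups(self):
        return (self.y0, self.y1, self.y2)


@dataclass(frozen=True)
class EffectEstimate:
    """An estimated nonparametric risk with its odds and variance."""

    f_hat: float
    var_f: float
    n_ref: int
    n_cmp: int
    label: str = ""

    @property
    def lambda_hat(self) -> float:
        if self.f_hat >= 1.0:
            warnings.warn(
                f"estimated risk is 1 for {self.label or 'effect'}; "
                "the odds estimator is not defined and is reported as inf",
                RuntimeWarning,
                stacklevel=2,
            )
            return np.inf
        return self.f_hat / (1.0 - self.f_hat)


@dataclass(frozen=True)
class PairCovariance:
    cov: float
    labels: tuple = ("", "")


def placements(ref, cmp):
    """Placement vectors (P, Q) for the pair of groups.

    P[j] is the fraction of ``cmp`` values exceeding ``ref[j]`` (ties 1/2);
    Q[k] is the fraction of ``ref`` values below ``cmp[k]``.  Both average to
    the estimated risk f_hat = Pr(ref < cmp).  O((m+n) log(m+n)).
    """
    ref = np.asarray(ref, dtype=float).ravel()
    cmp = np.asarray(cmp, dtype=float).ravel()
    if ref.size == 0:
        raise EstimationError("reference group is empty")
    if cmp.size == 0:
        raise EstimationError("comparison group is empty")
    cs = np.sort(cmp)
    # number of cmp strictly below / at-or-below each ref value
    lo = np.searchsorted(cs, ref, side="left")
    hi = np.searchsorted(cs, ref, side="right")
    p = (cmp.size - 0.5 * (lo + hi)) / cmp.size
    rs = np.sort(ref)
    lo = np.searchsorted(rs, cmp, side="left")
    hi = np.searchsorted(rs, cmp, side="right")
    q = 0.5 * (lo + hi) / ref.size
    return p, q


def estimate_f(ref, cmp, label: str = "") -> EffectEstimate:
    """Estimate f = Pr(ref < cmp) with the tie-aware pairwise proportion.

    The variance is attached when both groups have at least two members,
    otherwise it is NaN.
    """
    p, q = placements(ref, cmp)
    f_hat = float(np.mean(q))
    if p.size >= 2 and q.size >= 2:
        v = float(np.var(p, ddof=1) / p.size + np.var(q, ddof=1) / q.size)
    else:
        v = np.nan
    return EffectEstimate(f_hat=f_hat, var_f=v, n_ref=p.size, n_cmp=q.size, label=label)


def variance_f(ref, cmp) -> float:
    """Placement estimate of Var(f_hat): s2_P/n_ref + s2_Q/n_cmp."""
    p, q = placements(ref, cmp)
    if p.size < 2 or q.size < 2:
        raise EstimationError("variance needs at least two observations per group")
    return float(np.var(p, ddof=1) / p.size + np.var(q, ddof=1) / q.size)


def covariance_shared_ref(ref, cmp_a, cmp_b, labels=("a", "b")) -> PairCovariance:
    """Covariance of two risk estimates sharing the reference group.

    f_hat_a = Pr(ref < cmp_a) and f_hat_b = Pr(ref < cmp_b) share only the
    reference observations, so Cov = s_{P(a),P(b)} / n_ref, the sample
    covariance of the reference group's two placement vectors.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    if ref.size < 2:
        raise EstimationError("shared reference group needs >= 2 observations")
    pa, _ = placements(ref, cmp_a)
    pb, _ = placements(ref, cmp_b)
    cov = float(np.cov(pa, pb, ddof=1)[0, 1] / ref.size)
    return PairCovariance(cov=cov, labels=tuple(labels))


def covariance_shared_cmp(ref_a, shared, ref_b, labels=("a", "b")) -> PairCovariance:
    """Covariance of two risk estimates sharing one group on opposite sides.

    f_hat_a = Pr(ref_a < shared) uses the shared group as comparison;
    f_hat_b = Pr(shared < ref_b) uses it as reference.  The shared group's
    placements in the two roles, Q(a) and P(b), drive the covariance
    Cov = s_{Q(a),P(b)} / n_shared.
    """
    shared = np.asarray(shared, dtype=float).ravel()
    if shared.size < 2:
        raise EstimationError("shared group needs >= 2 observations")
    _, qa = placements(ref_a, shared)
    pb, _ = placements(shared, ref_b)
    cov = float(np.cov(qa, pb, ddof=1)[0, 1] / shared.size)
    return PairCovariance(cov=cov, labels=tuple(labels))


def _additive_weights(sample: GroupedSample):
    n0, n1, n2 = sample.n0, sample.n1, sample.n2
    tot = n0 + 2 * n1 + n2  # group 1 enters both pairwise estimates
    return (n0 + n1) / tot, (n1 + n2) / tot


def model_effect(sample: GroupedSample, model: str, label: str | None = None) -> EffectEstimate:
    """Genetic-model-specific nonparametric risk.

    recessive : f_2R = Pr(Y_{0 or 1} < Y_2), genotype 2 against the pooled rest.
    dominant  : f_1D = Pr(Y_0 < Y_{1 or 2}), carriers pooled against genotype 0.
    additive  : f_1A = w1 f_1 + w12 f_12 with sample-size-proportion weights
                w1 = (n0+n1)/(n0+2n1+n2), w12 = (n1+n2)/(n0+2n1+n2); its
                variance adds the shared-group-1 covariance term.
    """
    if model == "recessive":
        if sample.n2 == 0 or sample.n0 + sample.n1 == 0:
            raise EstimationError("recessive effect undefined: empty pooled group")
        pooled = np.concatenate([sample.y0, sample.y1])
        est = estimate_f(pooled, sample.y2, label=label or "f2R")
        return est
    if model == "dominant":
        if sample.n0 == 0 or sample.n1 + sample.n2 == 0:
            raise EstimationError("dominant effect undefined: empty pooled group")
        pooled = np.concatenate([sample.y1, sample.y2])
        return estimate_f(sample.y0, pooled, label=label or "f1D")
    if model == "additive":
        if min(sample.n0, sample.n1, sample.n2) == 0:
            raise EstimationError("additive effect undefined: empty genotype group")
        w1, w12 = _additive_weights(sample)
        e1 = estimate_f(sample.y0, sample.y1, label="f1")
        e12 = estimate_f(sample.y1, sample.y2, label="f12")
        f = w1 * e1.f_hat + w12 * e12.f_hat
        if sample.n0 >= 2 and sample.n1 >= 2 and sample.n2 >= 2:
            c = covariance_shared_cmp(sample.y0, sample.y1, sample.y2, labels=("f1", "f12")).cov
            v = w1 ** 2 * e1.var_f + w12 ** 2 * e12.var_f + 2.0 * w1 * w12 * c
            v = max(v, 0.0)
        else:
            v = np.nan
        return EffectEstimate(
            f_hat=float(f), var_f=float(v), n_ref=sample.n0 + sample.n1,
            n_cmp=sample.n1 + sample.n2, label=label or "f1A",
        )
    raise ValueError(f"unknown genetic model {model!r}")


@dataclass(frozen=True)
class _Influence:
    """Per-individual linearization of one model effect, by genotype group.

    u[g][i] approximates the contribution of individual i of genotype group g
    to f_hat - f, so that sum_g (n_g/(n_g-1)) * u_a[g] . u_b[g] estimates
    Cov(f_hat_a, f_hat_b) for any pair of model effects on the same sample.
    """

    f_hat: float
    u: tuple = field(repr=False, default=())


def effect_influence(sample: GroupedSample, model: str) -> _Influence:
    """Influence vectors of a model effect, used for cross-effect covariance."""
    y0, y1, y2 = sample.groups()
    n0, n1, n2 = sample.n0, sample.n1, sample.n2
    if model == "recessive":
        pooled = np.concatenate([y0, y1])
        p, q = placements(pooled, y2)
        f = float(np.mean(q))
        nref = n0 + n1
        u0 = (p[:n0] - f) / nref
        u1 = (p[n0:] - f) / nref
        u2 = (q - f) / n2
    elif model == "dominant":
        pooled = np.concatenate([y1, y2])
        p, q = placements(y0, pooled)
        f = float(np.mean(q))
        ncmp = n1 + n2
        u0 = (p - f) / n0
        u1 = (q[:n1] - f) / ncmp
        u2 = (q[n1:] - f) / ncmp
    elif model == "additive":
        w1, w12 = _additive_weights(sample)
        p1, q1 = placements(y0, y1)
        p12, q12 = placements(y1, y2)
        f1, f12 = float(np.mean(q1)), float(np.mean(q12))
        f = w1 * f1 + w12 * f12
        u0 = w1 * (p1 - f1) / n0
        u1 = w1 * (q1 - f1) / n1 + w12 * (p12 - f12) / n1
        u2 = w12 * (q12 - f12) / n2
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    return _Influence(f_hat=f, u=(u0, u1, u2))


def influence_cov(a: _Influence, b: _Influence) -> float:
    """Estimated covariance between two model effects on one sample."""
    tot = 0.0
    for ua, ub in zip(a.u, b.u):
        n = ua.size
        if n >= 2:
            tot += n / (n - 1.0) * float(np.dot(ua - ua.mean(), ub - ub.mean()))
    return tot
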
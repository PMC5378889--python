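"""Simulation engine: genotype/trait generation and replicated study cells.

The generating model is the linear model

    y = beta0 + beta1 * x(g) + eps

with g drawn under Hardy-Weinberg equilibrium at a given minor allele
frequency and eps i.i.d. from an error distribution (truncated Gumbel by
default; normal and centred-t alternates available).  The genotype score
x(g) encodes the generating genetic model on the allele-count scale:

    additive_count      : x = g                (0, 1, 2)
    recessive_indicator : x = 2 * I(g = 2)     (0, 0, 2)
    dominant_indicator  : x = 2 * I(g >= 1)    (0, 2, 2)

so the genotype-2 contrast is always 2*beta1 and the heterozygote contrast
is 0, 2*beta1 or beta1 under the three codings.  Defaults mirror the study
conditions used throughout: beta0 = 0.5, n = 1500, 2000 replicates,
alpha = 0.05, tGEV(0, 0, 1, 0) errors (scale 5 for power settings).

``run_cell`` replicates one cell: per replicate it simulates a cohort,
estimates the requested nonparametric odds with all three confidence
intervals, runs the requested tests, and aggregates bias, sMSE, coverage,
interval length and rejection rates.  Replicates are seeded individually
from the cell seed (numpy SeedSequence spawning), so cells are reproducible
and resumable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .association import z_test
from .competitors import competitor_test
from .effects import EstimationError, GroupedSample, estimate_f, model_effect
from .error_models import TGEVParams, true_odds_for_shift
from .intervals import CI_METHODS, interval
from .max3 import max3_test

__all__ = ["SimConfig", "CellSummary", "gen_genotypes", "gen_trait", "run_cell",
           "CODINGS", "EFFECTS"]

CODINGS = ("additive_count", "recessive_indicator", "dominant_indicator")

# effect label -> (estimator, genotype-2 contrast multiplier of beta1 per coding)
EFFECTS = ("f1", "f2", "f2R", "f1A", "f1D")


@dataclass(frozen=True)
class SimConfig:
    """One simulation cell: genetics, trait model, size and replication."""

    maf: float
    beta1: float
    beta0: float = 0.5
    coding: str = "additive_count"
    error: object = field(default_factory=TGEVParams)
    n: int = 1500
    replicates: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.coding not in CODINGS:
            raise ValueError(f"coding must be one of {CODINGS}")

    def shift(self, effect: str) -> float:
        """True location contrast behind one effect label under this coding."""
        x = _scores(self.coding)
        contrasts = {
            "f1": x[1] - x[0],
            "f2": x[2] - x[0],
            "f2R": x[2] - x[0],   # groups 0,1 share x under the recessive coding
            "f1D": x[1] - x[0],   # groups 1,2 share x under the dominant coding
            "f1A": x[1] - x[0],
        }
        return self.beta1 * contrasts[effect]

    def true_lambda(self, effect: str) -> float:
        return true_odds_for_shift(self.shift(effect), self.error)


def _scores(coding: str) -> np.ndarray:
    if coding == "additive_count":
        return np.array([0.0, 1.0, 2.0])
    if coding == "recessive_indicator":
        return np.array([0.0, 0.0, 2.0])
    if coding == "dominant_indicator":
        return np.array([0.0, 2.0, 2.0])
    raise ValueError(f"unknown coding {coding!r}")


def gen_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """HWE genotypes: minor-allele counts Binomial(2, maf) per subject."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, maf, size=n).astype(np.int8)


def gen_trait(genotypes: np.ndarray, config: SimConfig, rng=None) -> np.ndarray:
    """Trait values from the linear model with the configured error law."""
    genotypes = np.asarray(genotypes)
    if not np.isin(genotypes, (0, 1, 2)).all():
        raise ValueError("genotypes must be coded 0/1/2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _scores(config.coding)[genotypes]
    eps = config.error.sample(genotypes.size, rng)
    return config.beta0 + config.beta1 * x + eps


@dataclass
class CellSummary:
    """Aggregated metrics for one replicated simulation cell."""

    config: SimConfig
    effect: str | None = None
    lambda_true: float | None = None
    bias: float | None = None
    smse: float | None = None
    cp: dict = field(default_factory=dict)          # CI method -> coverage
    il: dict = field(default_factory=dict)          # CI method -> mean length
    il_excluded: dict = field(default_factory=dict)  # infinite-width intervals dropped
    rejection_rate: dict = field(default_factory=dict)  # test name -> rate
    redraws: int = 0
    failures: int = 0
    mean_group_sizes: tuple = ()


def _draw_sample(config: SimConfig, rng: np.random.Generator, counters) -> GroupedSample:
    # re-draw (with a logged counter) until every genotype group is populated:
    # the estimators need all three groups, and an empty group can occur at
    # low MAF
    while True:
        g = gen_genotypes(config.n, config.maf, rng)
        if (g == 0).any() and (g == 1).any() and (g == 2).any():
            break
        counters["redraws"] += 1
    y = gen_trait(g, config, rng)
    return GroupedSample.from_genotypes(y, g)


def _estimate(sample: GroupedSample, effect: str):
    if effect == "f1":
        return estimate_f(sample.y0, sample.y1, label="f1")
    if effect == "f2":
        return estimate_f(sample.y0, sample.y2, label="f2")
    if effect == "f2R":
        return model_effect(sample, "recessive")
    if effect == "f1A":
        return model_effect(sample, "additive")
    if effect == "f1D":
        return model_effect(sample, "dominant")
    raise ValueError(f"unknown effect label {effect!r}")


def _run_test(sample: GroupedSample, name: str):
    if name in ("ZR", "ZA", "ZD"):
        model = {"ZR": "recessive", "ZA": "additive", "ZD": "dominant"}[name]
        return z_test(sample, model)
    if name == "MAX3":
        return max3_test(sample)
    which, mod = name.split("-")
    model = {"R": "recessive", "A": "additive", "D": "dominant"}[mod]
    return competitor_test(sample, which, model)


def run_cell(config: SimConfig, effect: str | None = None, tests=(),
             ci_methods=CI_METHODS) -> CellSummary:
    """Replicate one simulation cell and aggregate its summary metrics.

    Parameters
    ----------
    effect : optional effect label ('f1', 'f2', 'f2R', 'f1A', 'f1D') whose
        odds is estimated each replicate, with bias/sMSE/coverage/length
        metrics against the integrated true odds.
    tests : test names among 'ZR', 'ZA', 'ZD', 'MAX3', and competitor codes
        like 'KW-A', 'F-R', 'JT-D'; rejection rates at ``config.alpha``.
    """
    tests = tuple(tests)
    summary = CellSummary(config=config, effect=effect)
    counters = {"redraws": 0, "failures": 0}
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)

    lam_true = config.true_lambda(effect) if effect else None
    summary.lambda_true = lam_true

    lam_hats = []
    covered = {m: 0 for m in ci_methods}
    lengths = {m: [] for m in ci_methods}
    inf_lengths = {m: 0 for m in ci_methods}
    rejections = {t: 0 for t in tests}
    valid = {t: 0 for t in tests}
    gsizes = np.zeros(3)

    for child in children:
        rng = np.random.default_rng(child)
        sample = _draw_sample(config, rng, counters)
        gsizes += (sample.n0, sample.n1, sample.n2)
        if effect is not None:
            try:
                est = _estimate(sample, effect)
                lam_hats.append(est.lambda_hat)
                for m in ci_methods:
                    ci = interval(est, config.alpha, method=m)
                    if ci.contains(lam_true):
                        covered[m] += 1
                    if np.isfinite(ci.length):
                        lengths[m].append(ci.length)
                    else:
                        inf_lengths[m] += 1
            except EstimationError:
                counters["failures"] += 1
        for t in tests:
            try:
                res = _run_test(sample, t)
            except EstimationError:
                counters["failures"] += 1
                continue
            valid[t] += 1
            if res.p_value < config.alpha:
                rejections[t] += 1

    reps = config.replicates
    if effect is not None and lam_hats:
        lam_hats = np.asarray(lam_hats)
        finite = lam_hats[np.isfinite(lam_hats)]
        summary.bias = float(np.mean(finite) - lam_true)
        summary.smse = float(np.sqrt(np.mean((finite - lam_true) ** 2)))
        n_ci = len(lam_hats)
        summary.cp = {m: covered[m] / n_ci for m in ci_methods}
        summary.il = {m: float(np.mean(lengths[m])) if lengths[m] else np.nan
                      for m in ci_methods}
        summary.il_excluded = {m: inf_lengths[m] for m in ci_methods}
    summary.rejection_rate = {t: rejections[t] / valid[t] if valid[t] else np.nan
                              for t in tests}
    summary.redraws = counters["redraws"]
    summary.failures = counters["failures"]
    summary.mean_group_sizes = tuple(gsizes / reps)
    return summary


def summary_frame(summaries) -> "pandas.DataFrame":
    """Long-format TSV-ready table (cell parameters, metric, value)."""
    import pandas as pd

    rows = []
    for s in summaries:
        cfg = s.config
        base = {
            "maf": cfg.maf, "beta0": cfg.beta0, "beta1": cfg.beta1,
            "coding": cfg.coding, "n": cfg.n, "replicates": cfg.replicates,
            "alpha": cfg.alpha, "seed": cfg.seed, "effect": s.effect or "",
        }
        if s.effect is not None:
            rows.append({**base, "metric": "lambda_true", "value": s.lambda_true})
            rows.append({**base, "metric": "bias", "value": s.bias})
            rows.append({**base, "metric": "smse", "value": s.smse})
            for m, v in s.cp.items():
                rows.append({**base, "metric": f"cp_{m}", "value": v})
            for m, v in s.il.items():
                rows.append({**base, "metric": f"il_{m}", "value": v})
        for t, v in s.rejection_rate.items():
            rows.append({**base, "metric": f"reject_{t}", "value": v})
        rows.append({**base, "metric": "redraws", "value": s.redraws})
    return pd.DataFrame(rows)
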
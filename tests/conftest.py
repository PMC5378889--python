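"""Shared fixtures and brute-force oracles for the placement estimators.

The oracles below recompute every placement quantity by the O(n^2)
definitional double loop; the package's O(n log n) implementations must
agree with them bit-for-bit (up to float associativity).
"""

import numpy as np
import pytest

from npodds.effects import GroupedSample


def brute_indicator(a, b):
    """I*(a < b) with ties counted 1/2."""
    return float(a < b) + 0.5 * float(a == b)


def brute_f(ref, cmp):
    s = sum(brute_indicator(a, b) for a in ref for b in cmp)
    return s / (len(ref) * len(cmp))


def brute_placements(ref, cmp):
    p = np.array([np.mean([brute_indicator(a, b) for b in cmp]) for a in ref])
    q = np.array([np.mean([brute_indicator(a, b) for a in ref]) for b in cmp])
    return p, q


def brute_variance(ref, cmp):
    p, q = brute_placements(ref, cmp)
    return np.var(p, ddof=1) / len(ref) + np.var(q, ddof=1) / len(cmp)


def brute_cov_shared_ref(ref, cmp_a, cmp_b):
    pa, _ = brute_placements(ref, cmp_a)
    pb, _ = brute_placements(ref, cmp_b)
    return np.cov(pa, pb, ddof=1)[0, 1] / len(ref)


def brute_cov_shared_cmp(ref_a, shared, ref_b):
    _, qa = brute_placements(ref_a, shared)
    pb, _ = brute_placements(shared, ref_b)
    return np.cov(qa, pb, ddof=1)[0, 1] / len(shared)


@pytest.fixture
def rng():
    return np.random.default_rng(20150712)


@pytest.fixture
def tiny_sample():
    """Small fixed sample with all three genotype groups and a tie."""
    return GroupedSample(
        y0=np.array([1.0, 4.0, 2.5, 0.5, 3.0]),
        y1=np.array([2.0, 5.0, 2.5, 4.5, 1.5]),
        y2=np.array([3.0, 6.0, 5.5, 2.0, 7.0]),
    )


@pytest.fixture
def null_sample(rng):
    """Moderately sized exchangeable sample (no genotype effect)."""
    return GroupedSample(
        y0=rng.gumbel(size=400),
        y1=rng.gumbel(size=300),
        y2=rng.gumbel(size=120),
    )


def random_small_groups(rng, n_sets=60, max_size=5, values=(0.0, 1.0, 2.0, 3.5)):
    """Random tie-rich group pairs covering all size combinations up to 5."""
    out = []
    sizes = [(a, b) for a in range(1, max_size + 1) for b in range(1, max_size + 1)]
    for i in range(n_sets):
        na, nb = sizes[i % len(sizes)]
        out.append((rng.choice(values, na), rng.choice(values, nb)))
    return out
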
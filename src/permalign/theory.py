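"""Success-probability calculus for the randomized permutation search.

A read that differs from its true nearest neighbor at ``p`` positions is
found by one permuted-index lookup when the random permutation moves all
``p`` mismatches past the first ``L`` output positions, where ``L`` is the
read's resolution length in that index.  Counting such "lucky" permutations
among all ``M!`` gives

    PrGoodPerm(p, L, M) = (M-L)! / (M-L-p)! * (M-p)! / M!

and with ``J`` independent permutations the probability that at least one
lookup proposes the true nearest neighbor is at least

    PrSuccess(p, L, M, J) >= 1 - (1 - PrGoodPerm(p, L, M))^J.

Both are lower bounds: the searched neighborhood (2K+1 entries) is at least
as wide as the prefix neighborhood of length L that the argument uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .index import PermutedIndex, resolution_length


class UnattainableTargetError(ValueError):
    """No number of iterations can reach the requested success probability."""


def _check_design(p: int, l: int, m: int):
    if not (0 <= p <= m):
        raise ValueError(f"need 0 <= p <= m, got p={p}, m={m}")
    if not (0 <= l <= m):
        raise ValueError(f"need 0 <= l <= m, got l={l}, m={m}")


def pr_good_perm_exact(p: int, l: int, m: int) -> Fraction:
    """PrGoodPerm as an exact rational (feasible for small m)."""
    _check_design(p, l, m)
    if p > m - l:
        return Fraction(0)  # pigeonhole: some mismatch must land in the prefix
    lucky = math.factorial(m - l) // math.factorial(m - l - p) * math.factorial(m - p)
    return Fraction(lucky, math.factorial(m))


def pr_good_perm(p: int, l: int, m: int) -> float:
    """Probability that a single random permutation moves all ``p`` mismatches
    out of the first ``l`` output positions (evaluated in log space)."""
    _check_design(p, l, m)
    if p == 0 or l == 0:
        return 1.0
    if p > m - l:
        return 0.0
    log_pr = (
        math.lgamma(m - l + 1)
        - math.lgamma(m - l - p + 1)
        + math.lgamma(m - p + 1)
        - math.lgamma(m + 1)
    )
    return float(math.exp(log_pr))


def pr_success(p: int, l: int, m: int, j: int) -> float:
    """Lower bound on the probability that at least one of ``j`` independent
    permuted-index lookups proposes the true nearest neighbor."""
    if j < 0:
        raise ValueError("j must be >= 0")
    q = pr_good_perm(p, l, m)
    if q >= 1.0:
        return 1.0 if j >= 1 else 0.0
    # 1 - (1-q)^j, stably
    return -float(math.expm1(j * math.log1p(-q)))


def required_iterations(p: int, l: int, m: int, target: float) -> int:
    """Smallest J with pr_success(p, l, m, J) >= target."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must be strictly between 0 and 1")
    q = pr_good_perm(p, l, m)
    if q <= 0.0:
        raise UnattainableTargetError(
            f"p={p} mismatches cannot avoid an l={l} prefix of an m={m} string"
        )
    if q >= target:
        return 1
    j = max(1, math.ceil(math.log1p(-target) / math.log1p(-q)))
    while pr_success(p, l, m, j) < target:  # guard against float edge cases
        j += 1
    while j > 1 and pr_success(p, l, m, j - 1) >= target:
        j -= 1
    return j


@dataclass(frozen=True)
class ResolutionProfile:
    """Empirical distribution of resolution lengths over sampled positions."""

    values: np.ndarray
    m: int
    k: int

    def histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.values, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def quantile(self, q) -> float:
        return float(np.quantile(self.values, q))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def resolution_profile(index: PermutedIndex, sample_size: int, k: int,
                       seed: int) -> ResolutionProfile:
    """Resolution lengths of a seeded random sample of library positions.

    Sampling is without replacement, so ``sample_size == |library|`` is the
    exact per-position distribution.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    n = index.library.size
    if sample_size > n:
        raise ValueError(f"sample_size {sample_size} exceeds library size {n}")
    rng = np.random.default_rng(seed)
    picks = index.library.positions[rng.choice(n, size=sample_size, replace=False)]
    picks.sort()
    values = np.array([resolution_length(index, int(p), k) for p in picks], dtype=np.int64)
    return ResolutionProfile(values=values, m=index.m, k=k)
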
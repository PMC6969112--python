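"""Randomization (permutation) tests and the midline classification statistic.

These mirror the resampling statistics commonly used on per-vial inheritance
fractions: a randomization test for a difference in means between two groups
of vial fractions, a randomization test for a difference in proportions on
pooled fly counts, and the classification of (x, y) inheritance pairs as
falling over / on / under the y = x midline.

p-values use the add-one convention p = (1 + #extreme) / (n_perm + 1), which
never reports 0 and is conservative.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RandTestResult",
    "randomization_test_means",
    "randomization_test_proportions",
    "diagonal_classification",
]

# slack for |diff| comparisons so exact ties are counted as extreme despite
# floating-point accumulation differences
_TIE_EPS = 1e-12


@dataclass
class RandTestResult:
    p_value: float
    observed_diff: float
    n_perm: int


def _perm_pvalue(pooled: np.ndarray, n_a: int, obs: float, n_perm: int, rng) -> float:
    # sorting the pool makes the p-value exactly invariant under swapping
    # equal-sized groups (the permutation law depends only on the multiset)
    pooled = np.sort(pooled)
    n = pooled.size
    extreme = 0
    thresh = abs(obs) - _TIE_EPS
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d = pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean()
        if abs(d) >= thresh:
            extreme += 1
    return (1 + extreme) / (n_perm + 1)


def randomization_test_means(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RandTestResult:
    """Two-sided randomization test for a difference in means.

    Pools the two groups, permutes group labels uniformly ``n_perm`` times and
    counts permutations whose |mean difference| is at least the observed one.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    p = _perm_pvalue(np.concatenate([a, b]), a.size, obs, n_perm, rng)
    return RandTestResult(p_value=p, observed_diff=float(obs), n_perm=n_perm)


def randomization_test_proportions(
    successes_a: int,
    total_a: int,
    successes_b: int,
    total_b: int,
    n_perm: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RandTestResult:
    """Two-sided randomization test for a difference in proportions.

    The pooled Bernoulli outcomes are permuted between the two groups; the
    statistic is the difference in group proportions.
    """
    for s, t in ((successes_a, total_a), (successes_b, total_b)):
        if t <= 0:
            raise ValueError("group totals must be positive")
        if not 0 <= s <= t:
            raise ValueError("successes must satisfy 0 <= successes <= total")
    if rng is None:
        rng = np.random.default_rng(seed)
    pooled = np.concatenate(
        [
            np.ones(successes_a),
            np.zeros(total_a - successes_a),
            np.ones(successes_b),
            np.zeros(total_b - successes_b),
        ]
    )
    obs = successes_a / total_a - successes_b / total_b
    p = _perm_pvalue(pooled, total_a, obs, n_perm, rng)
    return RandTestResult(p_value=p, observed_diff=float(obs), n_perm=n_perm)


def diagonal_classification(
    points: Sequence[tuple[float, float]], tol: float = 0.0
) -> tuple[float, float, float]:
    """Fractions of (x, y) points falling over, on and under the midline y = x.

    A point is *over* when y - x > tol, *on* when |y - x| <= tol, *under*
    when x - y > tol.  Returns ``(over, on, under)`` fractions summing to 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("points must be non-empty")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (x, y) pairs")
    d = pts[:, 1] - pts[:, 0]
    n = d.size
    n_over = int(np.sum(d > tol))
    n_under = int(np.sum(-d > tol))
    return (n_over / n, (n - n_over - n_under) / n, n_under / n)
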
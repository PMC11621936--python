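"""Shared exact-test engines.

Two tests recur throughout the pipeline — a two-sided Fisher exact test on
2x2 contingency tables (kinetic-class proportions, shared copy-number loss)
and a two-sided Mann-Whitney U test (CNV locus counts between sensitivity
groups).  Both live here so every module uses the same engine and the same
small-sample conventions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["fisher_exact_2x2", "mannwhitney_u", "EXACT_MWU_MAX_N"]

#: combined sample size up to which the Mann-Whitney p-value is computed by
#: exhaustive enumeration of rank splits (C(12, 6) = 924 splits at worst).
EXACT_MWU_MAX_N = 12


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of counts.

    The p-value is the sum of probabilities, under the hypergeometric null
    with all margins fixed, of every table whose probability does not exceed
    the observed table's.  A table with a zero margin carries no information
    and returns p = 1 by convention.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")[1]
    return float(min(1.0, p))


def _exact_mwu_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all assignments of pooled ranks.

    Ties are handled through mean ranks: the observed (tied) rank vector is
    fixed and every ``n_a``-subset of positions is treated as group A, which
    is the exact permutation null.  Two-sided p is twice the smaller tail
    (each tail including the observed value), capped at 1.
    """
    n = ranks.size
    offset = n_a * (n_a + 1) / 2.0
    us = np.fromiter(
        (ranks[list(idx)].sum() - offset for idx in combinations(range(n), n_a)),
        dtype=float,
    )
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mannwhitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_a, p)``.

    For combined sample sizes up to :data:`EXACT_MWU_MAX_N` the p-value is
    exact (enumeration over all rank splits, ties allowed); beyond that the
    tie-corrected normal approximation with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    if a.size + b.size <= EXACT_MWU_MAX_N:
        p = _exact_mwu_p(ranks, a.size, u_a)
    else:
        p = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return u_a, p
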
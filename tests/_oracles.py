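"""Independent brute-force oracles for the exact-test engines.

These deliberately re-derive the null distributions along a different code
path than the package engines: the Fisher oracle enumerates hypergeometric
tables with fixed margins, and the Mann-Whitney oracle delegates to scipy's
permutation machinery (the package's small-sample path is its own
enumeration).
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def fisher_enum_p(table) -> float:
    """Two-sided Fisher p by explicit enumeration over fixed margins."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def mwu_perm_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p via scipy's permutation test."""
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=stats.PermutationMethod()
    )
    return float(res.pvalue)


def km_hand(times, events):
    """Hand product-limit estimator: returns {event_time: S(t)}."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        out[t] = s
    return out
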
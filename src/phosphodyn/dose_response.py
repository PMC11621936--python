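"""Dose-response summaries: GI50, AUC, and sensitivity segregation.

GI50 — the concentration giving 50% growth inhibition relative to untreated
control — is read off the measured viability curve by log-linear
interpolation between the doses bracketing the first downward crossing of
50%, the pharmacological convention.  AUC is the trapezoidal area under the
viability-fraction curve over log10 dose, normalized by the log-dose span so
it lies in [0, 1] (lower = more sensitive) and is comparable across drugs.
Cell lines are segregated into sensitive and resistant groups per drug at
the largest gap in their log10 GI50 profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import pearson

__all__ = [
    "DoseResponseProfile",
    "GI50Result",
    "SensitivityCall",
    "compute_gi50",
    "compute_auc",
    "segregate_by_gi50",
    "auc_correlation",
]


@dataclass(frozen=True)
class DoseResponseProfile:
    """Viability versus concentration for one cell line x drug."""

    cell_line: str
    drug: str
    doses: tuple[float, ...]
    viability_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.size < 3:
            raise ValueError("a dose-response profile needs at least 3 doses")
        if (d <= 0).any() or (np.diff(d) <= 0).any():
            raise ValueError("doses must be positive and strictly increasing")
        if len(self.viability_pct) != d.size:
            raise ValueError("viability vector must match the dose grid")


@dataclass(frozen=True)
class GI50Result:
    """A GI50 estimate: ``value`` plus a censoring state.

    ``censoring`` is ``"none"`` for an interpolated crossing, ``"right"``
    when viability never reaches 50% (GI50 beyond the top dose — maximally
    resistant within the tested range), and ``"left"`` when viability is
    already below 50% at the lowest dose (maximally sensitive).
    """

    value: float
    censoring: str = "none"

    @property
    def censored(self) -> bool:
        return self.censoring != "none"

    @property
    def log10(self) -> float:
        """log10 GI50 with censored values pushed to the matching infinity."""
        if self.censoring == "right":
            return math.inf
        if self.censoring == "left":
            return -math.inf
        return math.log10(self.value)


@dataclass(frozen=True)
class SensitivityCall:
    cell_line: str
    drug: str
    gi50: GI50Result
    auc: float
    label: str  # "sensitive" | "resistant"


def compute_gi50(profile: DoseResponseProfile) -> GI50Result:
    """GI50 as the first downward crossing of 50% viability.

    Log-linear interpolation between the bracketing doses; a dose measured
    exactly at 50% is returned as-is.  Non-monotone curves are resolved by
    taking the first crossing.  No crossing -> right-censored at the top
    dose; below 50% everywhere -> left-censored at the lowest dose.
    """
    d = np.asarray(profile.doses, dtype=float)
    v = np.asarray(profile.viability_pct, dtype=float)
    for j in range(d.size):
        if v[j] == 50.0:
            return GI50Result(float(d[j]))
        if v[j] < 50.0:
            if j == 0:
                return GI50Result(float(d[0]), censoring="left")
            frac = (v[j - 1] - 50.0) / (v[j - 1] - v[j])
            log_gi50 = math.log10(d[j - 1]) + frac * (
                math.log10(d[j]) - math.log10(d[j - 1])
            )
            return GI50Result(10.0 ** log_gi50)
    return GI50Result(float(d[-1]), censoring="right")


def compute_auc(profile: DoseResponseProfile) -> float:
    """Normalized area under the viability curve over log10 dose, in [0, 1]."""
    d = np.log10(np.asarray(profile.doses, dtype=float))
    v = np.asarray(profile.viability_pct, dtype=float) / 100.0
    span = d[-1] - d[0]
    if span <= 0:
        raise ValueError("AUC needs at least two distinct doses")
    return float(np.trapezoid(v, d) / span)


def segregate_by_gi50(
    calls: pd.Series | dict, threshold: float | None = None
) -> pd.Series:
    """Split cell lines into sensitive/resistant at the largest GI50 gap.

    ``calls`` maps cell line -> :class:`GI50Result` (plain floats accepted).
    Lines are ordered by log10 GI50 (right-censored at +inf, left-censored at
    -inf) and split at the largest adjacent gap; the lower block is labelled
    sensitive.  ``threshold`` (a log10 GI50 cut) overrides the gap rule.
    Returns a Series of ``"sensitive"``/``"resistant"`` indexed by cell line.
    """
    s = pd.Series(dict(calls))
    if s.size < 2:
        raise ValueError("segregation needs at least 2 cell lines")
    logs = s.map(
        lambda g: g.log10 if isinstance(g, GI50Result) else math.log10(g)
    ).astype(float)
    if threshold is not None:
        return pd.Series(
            np.where(logs <= threshold, "sensitive", "resistant"), index=s.index
        )
    order = logs.sort_values(kind="stable")
    finite = order[np.isfinite(order)]
    labels = pd.Series("sensitive", index=s.index)
    labels[order.index[np.isposinf(order)]] = "resistant"
    has_right_censored = bool(np.isposinf(order).any())
    if has_right_censored:
        # the gap up to the censored block is infinite, hence the largest:
        # the split falls there and every finite line stays sensitive
        return labels
    if finite.nunique() <= 1:
        warnings.warn("all GI50 values equal; labelling every line sensitive")
        return labels
    gaps = np.diff(finite.to_numpy())
    cut = int(np.argmax(gaps))  # first largest gap
    labels[finite.index[cut + 1 :]] = "resistant"
    return labels


def auc_correlation(auc_drug1, auc_drug2) -> tuple[float, float]:
    """Pearson r and two-sided p between paired AUC vectors of two drugs."""
    return pearson(auc_drug1, auc_drug2)
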
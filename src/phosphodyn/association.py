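"""Correlation ranking of proteins against drug sensitivity and anchors.

Protein-level markers of resistance are screened by ranking every antibody's
Pearson correlation with log10 GI50 across the cell-line panel (at baseline
or any post-treatment time point), and co-regulated partners of an anchor
phosphoprotein are found by ranking correlations with the anchor across all
samples.  Significance is the usual t-test on r with n - 2 degrees of
freedom; a Benjamini-Hochberg q column is emitted as auxiliary information
only — the rankings themselves are by r, not adjusted p.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["pearson", "rank_vs_gi50", "coexpression_ranking"]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from t = r * sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _rank_against(matrix: pd.DataFrame, target: pd.Series, exclude=()) -> pd.DataFrame:
    rows = []
    for ab in matrix.columns:
        if ab in exclude:
            continue
        col = matrix[ab].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            continue  # constant antibody carries no correlation signal
        r, p = pearson(col, target.to_numpy(dtype=float))
        rows.append((ab, r, p, col.size))
    if not rows:
        raise ValueError("no non-constant antibody column to correlate")
    out = pd.DataFrame(rows, columns=["antibody", "r", "p", "n"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)


def rank_vs_gi50(
    matrix: pd.DataFrame, log10_gi50: pd.Series, drug: str = "", time_h: float = 0.0
) -> pd.DataFrame:
    """Rank antibodies by Pearson r against log10 GI50 across cell lines.

    ``matrix`` holds one row per cell line (expression at one time point,
    log2 scale) and one column per antibody; ``log10_gi50`` is indexed by
    cell line.  Lines with a non-finite (censored) GI50 are excluded with a
    warning.  Returns a frame ``antibody, r, p, n, q, anchor`` sorted by r
    descending; constant antibody columns are dropped.
    """
    common = matrix.index.intersection(log10_gi50.index)
    gi = log10_gi50.loc[common].astype(float)
    finite = np.isfinite(gi)
    if not finite.all():
        warnings.warn(
            f"excluding {int((~finite).sum())} cell line(s) with censored GI50"
        )
        gi = gi[finite]
    if gi.size < 3:
        raise ValueError("need >= 3 cell lines with a finite GI50")
    out = _rank_against(matrix.loc[gi.index], gi)
    out["anchor"] = f"GI50:{drug}@{time_h:g}h" if drug else f"GI50@{time_h:g}h"
    return out


def coexpression_ranking(matrix: pd.DataFrame, anchor: str) -> pd.DataFrame:
    """Rank antibodies by Pearson r with an anchor antibody over all samples."""
    if anchor not in matrix.columns:
        raise KeyError(f"anchor antibody {anchor!r} not present in matrix")
    out = _rank_against(matrix, matrix[anchor], exclude={anchor})
    out["anchor"] = anchor
    return out
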
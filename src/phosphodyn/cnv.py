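"""Copy-number analysis: ΔCNV, locus counts, shared-loss association.

Copy-number profiles are piecewise-constant integer segments in SEG-style
1-based inclusive coordinates on a diploid baseline.  ΔCNV between a
resistant line and its matched parental line is the position-wise difference
(resistant − parental) on the union of their breakpoints.  "CNV loci" are
events, not segments: adjacent qualifying segments (copy ≤ loss cutoff or
≥ gain cutoff) merge into a single locus.  Group contrasts use the shared
exact engines — per-gene Fisher tests on binary loss indicators, and a
Mann-Whitney U test on per-line locus counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fisher_exact_2x2, mannwhitney_u
from .association import pearson

__all__ = [
    "CNVProfile",
    "DeltaCNV",
    "delta_cnv",
    "count_cnv_loci",
    "loss_matrix",
    "shared_loss_test",
    "compare_group_counts",
    "gene_cn_vs_auc",
]

SEG_COLUMNS = ["chrom", "start", "end", "copy_number"]


@dataclass
class CNVProfile:
    """Per-position integer copy number for one cell line, as segments."""

    cell_line: str
    segments: pd.DataFrame  # chrom, start, end, copy_number (1-based inclusive)

    def __post_init__(self) -> None:
        seg = self.segments[SEG_COLUMNS].copy()
        seg = seg.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if (seg["start"] > seg["end"]).any():
            raise ValueError("segment start must not exceed end")
        if (seg["copy_number"] < 0).any():
            raise ValueError("copy numbers must be nonnegative")
        for _, chrom_seg in seg.groupby("chrom"):
            if (chrom_seg["start"].to_numpy()[1:] <= chrom_seg["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments in {self.cell_line}")
        self.segments = seg

    def copy_at(self, chrom: str, pos: int, default: int = 2) -> int:
        seg = self.segments
        hit = seg[(seg["chrom"] == chrom) & (seg["start"] <= pos) & (seg["end"] >= pos)]
        return int(hit["copy_number"].iloc[0]) if len(hit) else default


@dataclass
class DeltaCNV:
    """Position-wise copy-number difference, resistant − parental."""

    resistant: str
    parental: str
    segments: pd.DataFrame  # chrom, start, end, delta
    warnings_: list = field(default_factory=list)

    @property
    def max_segment(self) -> pd.Series:
        return self.segments.loc[self.segments["delta"].idxmax()]

    @property
    def min_segment(self) -> pd.Series:
        return self.segments.loc[self.segments["delta"].idxmin()]


def _breakpoint_union(a: pd.DataFrame, b: pd.DataFrame, chrom: str) -> np.ndarray:
    cuts = set()
    for seg in (a, b):
        sub = seg[seg["chrom"] == chrom]
        cuts.update(sub["start"].tolist())
        cuts.update((sub["end"] + 1).tolist())
    return np.array(sorted(cuts), dtype=int)


def delta_cnv(
    resistant: CNVProfile, parental: CNVProfile, default_copy: int = 2
) -> DeltaCNV:
    """ΔCNV over the union of breakpoints of the two profiles.

    Chromosomes present in only one profile are imputed diploid
    (``default_copy``) in the other, with a warning.  The result is
    antisymmetric: ``delta_cnv(a, b).delta == -delta_cnv(b, a).delta``.
    """
    chroms_r = set(resistant.segments["chrom"])
    chroms_p = set(parental.segments["chrom"])
    notes = []
    for chrom in sorted(chroms_r ^ chroms_p):
        msg = f"chromosome {chrom} present in only one profile; other treated as copy {default_copy}"
        notes.append(msg)
        warnings.warn(msg)
    rows = []
    for chrom in sorted(chroms_r | chroms_p):
        cuts = _breakpoint_union(resistant.segments, parental.segments, chrom)
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            cr = resistant.copy_at(chrom, int(lo), default_copy)
            cp = parental.copy_at(chrom, int(lo), default_copy)
            rows.append((chrom, int(lo), int(hi) - 1, cr - cp))
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "delta"])
    return DeltaCNV(
        resistant=resistant.cell_line,
        parental=parental.cell_line,
        segments=seg,
        warnings_=notes,
    )


def count_cnv_loci(
    profile: CNVProfile, loss_cutoff: int = 1, gain_cutoff: int = 3
) -> tuple[int, int]:
    """Count loss and gain loci (merged events) in one profile.

    A segment qualifies as loss when copy ≤ ``loss_cutoff`` and as gain when
    copy ≥ ``gain_cutoff``.  Adjacent qualifying segments of the same kind
    (next start = previous end + 1, same chromosome) merge into one locus,
    so counts are invariant to splitting a segment into equal-copy pieces.
    """
    n_loss = n_gain = 0
    for _, seg in profile.segments.groupby("chrom"):
        prev_end = None
        prev_kind = None
        for _, row in seg.iterrows():
            cn = row["copy_number"]
            kind = "loss" if cn <= loss_cutoff else "gain" if cn >= gain_cutoff else None
            adjacent = prev_end is not None and row["start"] == prev_end + 1
            if kind is not None and not (adjacent and kind == prev_kind):
                if kind == "loss":
                    n_loss += 1
                else:
                    n_gain += 1
            prev_end = row["end"]
            prev_kind = kind
    return n_loss, n_gain


def loss_matrix(
    profiles: list[CNVProfile], genes: pd.DataFrame, loss_cutoff: int = 1
) -> pd.DataFrame:
    """Binary genes x cell-lines loss-indicator matrix.

    ``genes`` has columns ``gene, chrom, start, end``; a gene is lost in a
    line when any overlapping segment has copy ≤ ``loss_cutoff``.
    """
    out = pd.DataFrame(
        0, index=genes["gene"], columns=[p.cell_line for p in profiles], dtype=int
    )
    for prof in profiles:
        seg = prof.segments
        lost = seg[seg["copy_number"] <= loss_cutoff]
        for _, g in genes.iterrows():
            hit = lost[
                (lost["chrom"] == g["chrom"])
                & (lost["start"] <= g["end"])
                & (lost["end"] >= g["start"])
            ]
            if len(hit):
                out.loc[g["gene"], prof.cell_line] = 1
    return out


def shared_loss_test(loss: pd.DataFrame, groups: pd.Series | dict) -> pd.Series:
    """Per-gene two-sided Fisher exact p for loss x group association.

    ``loss`` is the binary genes x lines matrix; ``groups`` maps cell line to
    one of two labels.  For each gene the 2x2 table is (lost / intact) x
    (group 1 / group 2).
    """
    groups = pd.Series(dict(groups)).reindex(loss.columns)
    if groups.isna().any():
        raise ValueError("every cell line needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    in_g1 = (groups == levels[0]).to_numpy()
    ps = {}
    for gene, row in loss.iterrows():
        lost = row.to_numpy(dtype=bool)
        table = [
            [int((lost & in_g1).sum()), int((lost & ~in_g1).sum())],
            [int((~lost & in_g1).sum()), int((~lost & ~in_g1).sum())],
        ]
        ps[gene] = fisher_exact_2x2(table)
    return pd.Series(ps, name="fisher_p")


def compare_group_counts(counts_a, counts_b) -> float:
    """Two-sided Mann-Whitney U p comparing per-line locus counts.

    Exact (enumeration) for combined n ≤ 12, tie-corrected normal
    approximation otherwise.
    """
    return mannwhitney_u(counts_a, counts_b)[1]


def gene_cn_vs_auc(copy_numbers, auc) -> tuple[float, float]:
    """Pearson r and p between a gene's copy number and AUC across lines."""
    return pearson(copy_numbers, auc)
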
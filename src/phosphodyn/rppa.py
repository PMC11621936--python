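"""Reverse-phase protein array (RPPA) quantification.

An RPPA slide carries one antibody and thousands of printed lysate dots:
every sample (condition x time point x cell line) is spotted in replicate
(tetraplicate in the reference design) together with control MIX dots that
pool lysate from all conditions.  This module models the printed layout,
collapses replicate spots into robust sample-level intensities, normalizes
them against the control MIX level, and assembles per-antibody time courses
expressed as log2 fold change from the pre-treatment (t = 0) sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SlideLayout",
    "TimeCourseSet",
    "build_layout",
    "aggregate_replicates",
    "spot_table_to_matrix",
    "control_levels",
    "normalize",
    "assemble_timecourses",
]

#: columns identifying one sample (one lysate, printed in replicate)
SAMPLE_KEY = ["cell_line", "drug", "dose_level", "time_h"]


@dataclass(frozen=True)
class SlideLayout:
    """Geometry of one printed slide."""

    n_conditions: int
    n_timepoints: int
    n_cell_lines: int
    n_replicates: int
    n_control_spots: int

    def __post_init__(self) -> None:
        for name in (
            "n_conditions",
            "n_timepoints",
            "n_cell_lines",
            "n_replicates",
            "n_control_spots",
        ):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_sample_spots(self) -> int:
        return (
            self.n_conditions
            * self.n_timepoints
            * self.n_cell_lines
            * self.n_replicates
        )

    @property
    def total_spots(self) -> int:
        return self.n_sample_spots + self.n_control_spots


def build_layout(
    n_conditions: int,
    n_timepoints: int,
    n_cell_lines: int,
    n_replicates: int,
    n_control_spots: int = 0,
) -> SlideLayout:
    """Build a :class:`SlideLayout`; e.g. ``(12, 5, 8, 4, 80)`` -> 2000 spots."""
    return SlideLayout(
        n_conditions, n_timepoints, n_cell_lines, n_replicates, n_control_spots
    )


def aggregate_replicates(
    values, mad_multiplier: float = 3.5
) -> tuple[float, int, int]:
    """Collapse replicate spot intensities into one sample-level value.

    Replicates farther than ``mad_multiplier * 1.4826 * MAD`` from the median
    are excluded as gross spotting errors and the median of the survivors is
    returned, together with the number of replicates used and excluded.  When
    the MAD is zero and all values are equal the rule is skipped; a zero MAD
    with unequal values excludes everything off the median.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("aggregate_replicates requires at least one value")
    if x.size == 1:
        return float(x[0]), 1, 0
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0 and np.all(x == x[0]):
        return med, int(x.size), 0
    keep = np.abs(x - med) <= mad_multiplier * 1.4826 * mad
    return float(np.median(x[keep])), int(keep.sum()), int((~keep).sum())


def spot_table_to_matrix(
    spots: pd.DataFrame, mad_multiplier: float = 3.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a per-spot table into a raw samples x antibodies matrix.

    ``spots`` follows the simulator schema (one row per dot; control MIX dots
    flagged by ``is_control``).  Returns ``(matrix, provenance)`` where the
    matrix is indexed by the sample key and the provenance frame records how
    many replicates survived outlier exclusion for every cell.
    """
    samples = spots.loc[~spots["is_control"].astype(bool)]
    records = []
    for key, grp in samples.groupby(SAMPLE_KEY + ["antibody"], sort=True):
        level, n_used, n_excl = aggregate_replicates(
            grp["intensity"].to_numpy(), mad_multiplier
        )
        records.append((*key, level, n_used, n_excl))
    prov = pd.DataFrame(
        records,
        columns=SAMPLE_KEY + ["antibody", "intensity", "n_used", "n_excluded"],
    )
    matrix = prov.pivot_table(
        index=SAMPLE_KEY, columns="antibody", values="intensity"
    )
    matrix.columns.name = None
    return matrix, prov


def control_levels(spots: pd.DataFrame, mad_multiplier: float = 3.5) -> pd.Series:
    """Per-antibody aggregated control MIX level from a per-spot table."""
    ctrl = spots.loc[spots["is_control"].astype(bool)]
    if ctrl.empty:
        raise ValueError("spot table contains no control spots")
    return ctrl.groupby("antibody")["intensity"].apply(
        lambda v: aggregate_replicates(v.to_numpy(), mad_multiplier)[0]
    )


def normalize(matrix: pd.DataFrame, controls: pd.Series) -> pd.DataFrame:
    """Normalize a raw intensity matrix against control MIX levels.

    Each antibody column is divided by that antibody's control level, then
    every sample (row) is median-centered in log space so per-sample loading
    and staining factors cancel.  Antibodies with a missing, zero, or
    non-finite control level are dropped with a warning.  Output is strictly
    positive and invariant to any per-antibody global rescaling of the input.
    """
    controls = controls.reindex(matrix.columns)
    bad = controls.index[~(controls > 0) | ~np.isfinite(controls)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} antibod{'y' if len(bad) == 1 else 'ies'} "
            f"with missing or zero control level: {list(bad)}"
        )
        matrix = matrix.drop(columns=bad)
        controls = controls.drop(index=bad)
    if matrix.shape[1] == 0:
        raise ValueError("no antibody has a usable control level")
    logged = np.log2(matrix / controls)
    centered = logged.sub(logged.median(axis=1), axis=0)
    return 2.0 ** centered


@dataclass
class TimeCourseSet:
    """A set of protein-expression time courses on a shared time grid.

    ``data`` is long format with one row per (course, time point):
    ``course_id, cell_line, drug, dose_level, antibody, time_h, log2fc``
    (an ``intensity`` column is carried when courses come from a matrix).
    """

    data: pd.DataFrame
    time_grid_h: tuple[float, ...]
    skipped: list = field(default_factory=list)

    @property
    def n_courses(self) -> int:
        return self.data["course_id"].nunique()

    @property
    def course_meta(self) -> pd.DataFrame:
        cols = ["course_id", "cell_line", "drug", "dose_level", "antibody"]
        return self.data[cols].drop_duplicates().set_index("course_id")

    def wide_log2fc(self) -> pd.DataFrame:
        """Courses x time-grid matrix of log2 fold changes."""
        wide = self.data.pivot_table(
            index="course_id", columns="time_h", values="log2fc"
        )
        return wide.reindex(columns=list(self.time_grid_h))


def assemble_timecourses(matrix: pd.DataFrame) -> TimeCourseSet:
    """Assemble per-antibody time courses from a normalized intensity matrix.

    One series is one (cell line, drug, dose level); each series contributes
    one course per antibody, so ``n_courses = n_series * n_antibodies`` minus
    any series skipped for lacking a t = 0 sample.  ``log2fc`` is computed
    against the series' own t = 0 sample, hence ``log2fc == 0`` at t = 0.
    """
    grid = tuple(sorted(matrix.index.get_level_values("time_h").unique()))
    frames, skipped = [], []
    for series_key, block in matrix.groupby(
        level=["cell_line", "drug", "dose_level"], sort=True
    ):
        block = block.droplevel(["cell_line", "drug", "dose_level"])
        block = block.sort_index()
        if 0 not in block.index:
            skipped.append(series_key)
            continue
        base = block.loc[0]
        fc = np.log2(block.div(base, axis=1))
        long = fc.stack().rename("log2fc").reset_index()
        long.columns = ["time_h", "antibody", "log2fc"]
        inten = block.stack().rename("intensity").reset_index()
        long["intensity"] = inten["intensity"]
        line, drug, dose = series_key
        long["cell_line"], long["drug"], long["dose_level"] = line, drug, dose
        long["course_id"] = (
            long["cell_line"]
            + "|"
            + long["drug"]
            + "|"
            + long["dose_level"]
            + "|"
            + long["antibody"].astype(str)
        )
        frames.append(long)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} series lacking a t=0 sample: {skipped[:5]}"
        )
    if not frames:
        raise ValueError("no series with a t=0 sample found")
    data = pd.concat(frames, ignore_index=True)[
        [
            "course_id",
            "cell_line",
            "drug",
            "dose_level",
            "antibody",
            "time_h",
            "intensity",
            "log2fc",
        ]
    ]
    return TimeCourseSet(data=data, time_grid_h=grid, skipped=skipped)
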
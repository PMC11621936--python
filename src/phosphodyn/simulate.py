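"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the reference study design: an RPPA slide of 2000
dots (12 drug-dose conditions x 5 time points x 8 cell lines printed in
tetraplicate, plus 80 control MIX / buffer dots); 5-point protein time
courses drawn from four kinetic archetypes (early / intermediate / late /
flat); sigmoidal viability curves with a known GI50; copy-number profiles
with a planted shared-loss region confined to one sensitivity group; and
cohorts with exponential event times, stratum-specific hazard ratios and
independent censoring.  Every generated entity is recorded in a
:class:`GroundTruth` object so downstream estimates can be scored.

All randomness flows from a single root seed through named substreams (one
per generator), so adding a generator does not perturb any other.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cnv import CNVProfile
from .dose_response import DoseResponseProfile
from .dynamics import KINETIC_CLASSES
from .rppa import TimeCourseSet

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GroundTruth",
    "gen_spot_table",
    "gen_timecourses",
    "gen_dose_response",
    "gen_cnv_profiles",
    "gen_cohort",
]

DOSE_LEVELS = ("low", "medium", "high")

#: admissible peak times (hours) per responsive kinetic class on the default grid
PEAK_TIMES_H = {"early": (3.0, 6.0), "intermediate": (12.0,), "late": (24.0,)}


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator derived from the root seed."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generators.

    Defaults reproduce the reference slide: 4 drugs x 3 dose levels = 12
    conditions, 5 time points over 24 h, 8 cell lines, tetraplicate spots,
    80 control dots.  ``class_mix`` gives the kinetic-class frequencies;
    amplitudes and noise are in log2 units.
    """

    seed: int = 0
    n_cell_lines: int = 8
    n_antibodies: int = 1
    time_grid_h: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 24.0)
    drugs: tuple[str, ...] = ("5FU", "CIS", "ETP", "DTX")
    doses_per_drug: int = 3
    replicates: int = 4
    n_control_spots: int = 80
    class_mix: dict = field(
        default_factory=lambda: {
            "early": 0.20,
            "intermediate": 0.15,
            "late": 0.15,
            "none": 0.50,
        }
    )
    amplitude_log2: float = 2.0
    noise_sd_log2: float = 0.3
    outlier_rate: float = 0.01
    baseline_sd_log2: float = 0.5
    sample_scale_sd_log2: float = 0.25

    def __post_init__(self) -> None:
        mix = dict(self.class_mix)
        if set(mix) - set(KINETIC_CLASSES):
            raise ConfigurationError(
                f"unknown kinetic class in class_mix: {set(mix) - set(KINETIC_CLASSES)}"
            )
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
            raise ConfigurationError("class_mix fractions must be >= 0 and sum to 1")
        grid = tuple(self.time_grid_h)
        if len(grid) < 3:
            raise ConfigurationError("time grid needs at least 3 points")
        if grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError(
                "time grid must be strictly increasing and start at 0"
            )
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not 0 <= self.outlier_rate <= 1:
            raise ConfigurationError("outlier_rate must lie in [0, 1]")
        if self.amplitude_log2 <= 0 or self.noise_sd_log2 < 0:
            raise ConfigurationError("amplitude must be > 0 and noise sd >= 0")

    @property
    def dose_levels(self) -> tuple[str, ...]:
        if self.doses_per_drug <= len(DOSE_LEVELS):
            return DOSE_LEVELS[: self.doses_per_drug]
        return tuple(f"d{i+1}" for i in range(self.doses_per_drug))

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return [(drug, level) for drug in self.drugs for level in self.dose_levels]

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(f"GC{i+1:02d}" for i in range(self.n_cell_lines))

    @property
    def antibodies(self) -> tuple[str, ...]:
        return tuple(f"Ab{i+1:03d}" for i in range(self.n_antibodies))


@dataclass
class GroundTruth:
    """What the generators actually planted, keyed like the outputs."""

    class_by_course: dict = field(default_factory=dict)
    direction_by_course: dict = field(default_factory=dict)
    log2fc_by_course: dict = field(default_factory=dict)
    gi50_by_line_drug: dict = field(default_factory=dict)
    planted_loss_region: tuple | None = None
    hr_by_stratum: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["log2fc_by_course"] = {
            k: list(map(float, v)) for k, v in self.log2fc_by_course.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _archetype_mean(
    label: str, grid: np.ndarray, amplitude: float, rng: np.random.Generator
) -> tuple[np.ndarray, float, int]:
    """Mean log2FC vector for one course: a single log-time Gaussian bump.

    Returns ``(mean, peak_time, direction)``; flat courses are all zero.
    The bump is ``A * exp(-(ln t - ln t_peak)^2 / (2 * 0.5^2))`` at t > 0,
    whose argmax on the grid is the sampled peak time, so the class windows
    (early <= 6 h, intermediate <= 12 h, late <= 24 h) hold by construction.
    """
    direction = int(rng.choice([-1, 1]))
    if label == "none":
        return np.zeros_like(grid), 0.0, direction
    peak = float(rng.choice(PEAK_TIMES_H[label]))
    mean = np.zeros_like(grid)
    pos = grid > 0
    mean[pos] = amplitude * np.exp(
        -((np.log(grid[pos]) - np.log(peak)) ** 2) / (2 * 0.5**2)
    )
    return direction * mean, peak, direction


def _course_truth(config: SimulationConfig, stream: str):
    """Sample per-course kinetic classes and mean fold-change vectors."""
    rng = _rng(config.seed, stream)
    grid = np.asarray(config.time_grid_h, dtype=float)
    labels = list(config.class_mix)
    probs = np.array([config.class_mix[l] for l in labels], dtype=float)
    truth = {}
    for line in config.cell_lines:
        for drug, level in config.conditions:
            for ab in config.antibodies:
                cid = f"{line}|{drug}|{level}|{ab}"
                label = str(rng.choice(labels, p=probs))
                mean, peak, direction = _archetype_mean(
                    label, grid, config.amplitude_log2, rng
                )
                truth[cid] = (label, mean, peak, direction)
    return truth, grid


def gen_timecourses(config: SimulationConfig) -> tuple[TimeCourseSet, GroundTruth]:
    """Generate log2-fold-change time courses from the kinetic archetypes.

    One course per (cell line, drug, dose level, antibody); the class is
    drawn from ``class_mix``, the mean profile from the class archetype, and
    i.i.d. Gaussian noise with sd ``noise_sd_log2`` is added at every
    post-baseline point (log2fc at t = 0 is identically zero).
    """
    truth_map, grid = _course_truth(config, "timecourses")
    rng = _rng(config.seed, "timecourses.noise")
    gt = GroundTruth()
    rows = []
    for cid, (label, mean, _peak, direction) in truth_map.items():
        line, drug, level, ab = cid.split("|")
        noise = rng.normal(0.0, config.noise_sd_log2, size=grid.size)
        noise[grid == 0] = 0.0
        fc = mean + noise
        gt.class_by_course[cid] = label
        gt.direction_by_course[cid] = direction
        gt.log2fc_by_course[cid] = mean
        for t, v in zip(grid, fc):
            rows.append((cid, line, drug, level, ab, float(t), float(v)))
    data = pd.DataFrame(
        rows,
        columns=[
            "course_id",
            "cell_line",
            "drug",
            "dose_level",
            "antibody",
            "time_h",
            "log2fc",
        ],
    )
    return TimeCourseSet(data=data, time_grid_h=tuple(grid)), gt


def gen_spot_table(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a per-spot intensity table, one printed slide per antibody.

    Each slide carries one spot per (condition, time point, cell line,
    replicate) plus ``n_control_spots`` control MIX dots — 2000 dots per
    slide under the default design.  A spot's intensity is the sample's true
    level (baseline x per-sample staining factor x 2^log2FC from the course
    archetypes) under multiplicative log-normal spot noise; with probability
    ``outlier_rate`` a replicate is hit by a x10 gross error.  The control
    MIX pool is modelled as tracking each antibody's pre-treatment
    abundance: its level is the geometric mean of the baseline (t = 0)
    sample levels for the antibody.
    """
    truth_map, grid = _course_truth(config, "timecourses")
    gt = GroundTruth()
    for cid, (label, mean, _peak, direction) in truth_map.items():
        gt.class_by_course[cid] = label
        gt.direction_by_course[cid] = direction
        gt.log2fc_by_course[cid] = mean
    rng = _rng(config.seed, "spots")
    baselines = {
        ab: 1000.0 * 2.0 ** rng.normal(0.0, config.baseline_sd_log2)
        for ab in config.antibodies
    }
    scales = {}  # per-sample staining factor, shared across antibodies
    for line in config.cell_lines:
        for drug, level in config.conditions:
            for t in grid:
                scales[(line, drug, level, t)] = 2.0 ** rng.normal(
                    0.0, config.sample_scale_sd_log2
                )
    n_cols = 40  # printing geometry: spots laid out row-major, 40 per row
    rows = []
    for ab in config.antibodies:
        levels = {}
        for line in config.cell_lines:
            for drug, level in config.conditions:
                cid = f"{line}|{drug}|{level}|{ab}"
                _, mean, _, _ = truth_map[cid]
                for t, fc in zip(grid, mean):
                    levels[(line, drug, level, t)] = (
                        baselines[ab] * scales[(line, drug, level, t)] * 2.0**fc
                    )
        baseline_levels = [v for (line, drug, lvl, t), v in levels.items() if t == 0]
        control_level = float(np.exp(np.mean(np.log(np.array(baseline_levels)))))
        spot_idx = 0
        for (line, drug, level, t), true_level in levels.items():
            for rep in range(1, config.replicates + 1):
                intensity = true_level * 2.0 ** rng.normal(
                    0.0, config.noise_sd_log2
                )
                if rng.random() < config.outlier_rate:
                    intensity *= 10.0
                rows.append(
                    (
                        ab,
                        1 + spot_idx // 400,
                        1 + (spot_idx % 400) // n_cols,
                        1 + spot_idx % n_cols,
                        f"{drug}:{level}",
                        drug,
                        level,
                        float(t),
                        line,
                        rep,
                        ab,
                        float(intensity),
                        False,
                    )
                )
                spot_idx += 1
        for _ in range(config.n_control_spots):
            intensity = control_level * 2.0 ** rng.normal(
                0.0, config.noise_sd_log2
            )
            rows.append(
                (
                    ab,
                    1 + spot_idx // 400,
                    1 + (spot_idx % 400) // n_cols,
                    1 + spot_idx % n_cols,
                    "MIX",
                    "",
                    "",
                    np.nan,
                    "",
                    0,
                    ab,
                    float(intensity),
                    True,
                )
            )
            spot_idx += 1
    spots = pd.DataFrame(
        rows,
        columns=[
            "slide",
            "block",
            "row",
            "col",
            "condition",
            "drug",
            "dose_level",
            "time_h",
            "cell_line",
            "replicate",
            "antibody",
            "intensity",
            "is_control",
        ],
    )
    return spots, gt


def gen_dose_response(
    true_gi50: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
    hill: float = 1.0,
    cell_line: str = "GC01",
    drug: str = "5FU",
) -> tuple[DoseResponseProfile, GroundTruth]:
    """Sigmoidal viability curve with a known midpoint.

    Viability follows a 4-parameter logistic with top 100, bottom 0, Hill
    slope ``hill`` and midpoint ``true_gi50`` — exactly 50% at the midpoint
    — plus additive Gaussian noise in percentage points.
    """
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any() or (np.diff(doses) <= 0).any():
        raise ConfigurationError("doses must be positive and strictly increasing")
    if true_gi50 <= 0:
        raise ConfigurationError("true_gi50 must be positive")
    rng = _rng(seed, "dose_response")
    viability = 100.0 / (1.0 + (doses / true_gi50) ** hill)
    viability = viability + rng.normal(0.0, noise_sd, size=doses.size)
    profile = DoseResponseProfile(
        cell_line=cell_line,
        drug=drug,
        doses=tuple(doses),
        viability_pct=tuple(float(v) for v in viability),
    )
    gt = GroundTruth(gi50_by_line_drug={f"{cell_line}|{drug}": float(true_gi50)})
    return profile, gt


def gen_cnv_profiles(
    n_lines: int,
    n_positions: int,
    planted_region: tuple,
    group_labels,
    seed: int = 0,
    background_rate: float = 0.002,
    bin_size: int = 1000,
    chrom: str = "chr4",
) -> tuple[list[CNVProfile], GroundTruth]:
    """Copy-number profiles with a planted shared-loss region in one group.

    The genome is ``n_positions`` bins of ``bin_size`` bp on one chromosome,
    diploid everywhere.  ``planted_region`` is ``(start_bin, end_bin,
    group)`` (0-based inclusive bins): lines whose label equals ``group``
    get copy number 1 across the region.  Elsewhere each bin independently
    suffers a background gain (3) or loss (1) with probability
    ``background_rate``.  Runs of equal copy number are emitted as SEG-style
    segments in 1-based inclusive coordinates.
    """
    group_labels = list(group_labels)
    if len(group_labels) != n_lines:
        raise ConfigurationError("group_labels must have one label per line")
    start_bin, end_bin, target_group = planted_region
    if not 0 <= start_bin <= end_bin < n_positions:
        raise ConfigurationError("planted region must lie inside the genome")
    rng = _rng(seed, "cnv")
    profiles = []
    for i, label in enumerate(group_labels):
        cn = np.full(n_positions, 2, dtype=int)
        if background_rate > 0:
            hit = rng.random(n_positions) < background_rate
            cn[hit] = rng.choice([1, 3], size=int(hit.sum()))
        if label == target_group:
            cn[start_bin : end_bin + 1] = 1
        segs = []
        run_start = 0
        for j in range(1, n_positions + 1):
            if j == n_positions or cn[j] != cn[run_start]:
                segs.append(
                    (
                        chrom,
                        run_start * bin_size + 1,
                        j * bin_size,
                        int(cn[run_start]),
                    )
                )
                run_start = j
        profiles.append(
            CNVProfile(
                cell_line=f"GC{i+1:02d}",
                segments=pd.DataFrame(
                    segs, columns=["chrom", "start", "end", "copy_number"]
                ),
            )
        )
    gt = GroundTruth(
        planted_loss_region=(
            chrom,
            start_bin * bin_size + 1,
            (end_bin + 1) * bin_size,
            target_group,
        )
    )
    return profiles, gt


def gen_cohort(
    n: int,
    arms: tuple[str, str] = ("surgery", "S-1"),
    hr_by_stratum: dict | None = None,
    censor_rate: float = 0.008,
    marker_prevalences: dict | None = None,
    seed: int = 0,
    baseline_hazard: float = np.log(2) / 36.0,
    followup_months: float = 120.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort with exponential event times and stratum-specific arm effects.

    Patients are assigned 1:1 to ``arms`` and uniformly to the strata named
    by ``hr_by_stratum`` (default TLC− HR 1.0, TLC+ HR 0.46).  Event times
    are exponential with hazard ``baseline_hazard`` (default median 36
    months), multiplied by the stratum HR in the second (treated) arm;
    censoring is an independent exponential clock at ``censor_rate`` plus
    administrative cut-off at ``followup_months``.  Binary markers are
    independent Bernoulli draws; the continuous TLC marker is drawn
    consistently with the TLC stratum when strata are named ``TLC±``.
    """
    if n < 2:
        raise ConfigurationError("cohort size must be >= 2")
    if hr_by_stratum is None:
        hr_by_stratum = {"TLC-": 1.0, "TLC+": 0.46}
    if any(hr <= 0 for hr in hr_by_stratum.values()):
        raise ConfigurationError("hazard ratios must be positive")
    if marker_prevalences is None:
        marker_prevalences = {"PD_L1": 0.30, "IkBa": 0.45, "H_pylori": 0.33}
    rng = _rng(seed, "cohort")
    strata = list(hr_by_stratum)
    stratum = rng.choice(strata, size=n)
    arm = rng.choice(list(arms), size=n)
    hr = np.array(
        [hr_by_stratum[s] if a == arms[1] else 1.0 for s, a in zip(stratum, arm)]
    )
    t_event = rng.exponential(1.0 / (baseline_hazard * hr))
    t_cens = (
        rng.exponential(1.0 / censor_rate, size=n)
        if censor_rate > 0
        else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_cens, followup_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # times must stay positive
    df = pd.DataFrame(
        {
            "id": [f"P{i+1:05d}" for i in range(n)],
            "arm": arm,
            "stratum": stratum,
            "time_months": time,
            "event": event,
        }
    )
    if all(s in ("TLC-", "TLC+") for s in strata):
        tlc = np.where(
            stratum == "TLC+",
            rng.normal(2000.0, 300.0, size=n),
            rng.normal(1200.0, 300.0, size=n),
        )
        df["TLC"] = np.clip(tlc, 200.0, None)
    for marker, prev in marker_prevalences.items():
        df[marker] = (rng.random(n) < prev).astype(int)
    gt = GroundTruth(hr_by_stratum=dict(hr_by_stratum))
    return df, gt
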
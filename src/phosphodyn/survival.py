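"""Survival stratification: Kaplan-Meier, log-rank, Cox hazard ratios.

The cohort analyses stratify patients by dichotomized markers (total
lymphocyte count at the cohort median, immunohistochemistry positivity) and
estimate the treatment effect of adjuvant chemotherapy versus surgery alone
within strata: product-limit survival curves with Greenwood variance,
log-rank tests, and unadjusted Cox proportional-hazards ratios with Wald
95% intervals.  Ties are handled with Efron's method — calendar-month
follow-up times are heavily tied.  Estimation is delegated to lifelines
behind this module's surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

__all__ = [
    "HazardEstimate",
    "SurvivalCurve",
    "median_split",
    "km_estimate",
    "logrank",
    "cox_hr",
    "subgroup_analysis",
    "hazard_screen",
]


def median_split(values) -> np.ndarray:
    """Dichotomize at the median: positive iff value > median.

    Values equal to the median go to the negative group (documented tie
    policy).  Returns a boolean array; warns when all values are equal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("median_split needs >= 2 finite values")
    med = np.median(x)
    labels = x > med
    if not labels.any():
        warnings.warn("all values equal to the median; every label negative")
    return labels


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier product-limit curve with Greenwood variance."""

    table: pd.DataFrame  # time, at_risk, events, censored, survival, greenwood_var
    n: int

    def survival_at(self, t: float) -> float:
        """Value of the step function at time ``t`` (e.g. 60 for 5-year)."""
        past = self.table[self.table["time"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival estimate from times and event flags."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0 or (times <= 0).any():
        raise ValueError("times must be positive and non-empty")
    kmf = KaplanMeierFitter().fit(times, events)
    ev = kmf.event_table[kmf.event_table.index > 0]
    d = ev["observed"].to_numpy(dtype=float)
    n_at_risk = ev["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev.index).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(
            n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf
        )
    increments = np.where(d > 0, increments, 0.0)
    greenwood = surv**2 * np.cumsum(increments)
    table = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": n_at_risk.astype(int),
            "events": d.astype(int),
            "censored": ev["censored"].to_numpy(dtype=int),
            "survival": surv,
            "greenwood_var": greenwood,
        }
    ).reset_index(drop=True)
    return SurvivalCurve(table=table, n=int(times.size))


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi2, p)`` with 1 df."""
    res = logrank_test(times_a, times_b, events_a, events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardEstimate:
    """A Cox hazard ratio with Wald 95% CI and p."""

    hr: float
    ci95: tuple[float, float]
    p: float
    n_per_group: dict = field(default_factory=dict)
    n_events: int = 0
    flagged: bool = False  # monotone likelihood / separation


def _encode_covariate(df: pd.DataFrame, covariate: str, positive=None):
    col = df[covariate]
    if col.dtype == bool:
        return col.astype(float), {False: "0", True: "1"}
    if not pd.api.types.is_numeric_dtype(col):
        levels = sorted(col.unique())
        if len(levels) != 2:
            raise ValueError(
                f"categorical covariate {covariate!r} must have 2 levels, got {levels}"
            )
        if positive is None:
            positive = levels[1]
        return (col == positive).astype(float), {
            "0": [l for l in levels if l != positive][0],
            "1": positive,
        }
    return col.astype(float), None


def cox_hr(
    df: pd.DataFrame,
    covariate: str,
    duration_col: str = "time_months",
    event_col: str = "event",
    positive=None,
) -> HazardEstimate:
    """Univariable Cox proportional-hazards ratio for one covariate.

    Binary string covariates are coded 0/1 (``positive`` names the level
    coded 1; default the lexicographically larger one), so the HR indexes
    the positive level against the reference.  Efron tie handling.  Monotone
    likelihood (complete separation) is flagged and the CI reported as
    unbounded rather than trusted.
    """
    coded, mapping = _encode_covariate(df, covariate, positive)
    fit_df = pd.DataFrame(
        {
            duration_col: df[duration_col].astype(float),
            event_col: df[event_col].astype(int),
            covariate: coded,
        }
    )
    if fit_df[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    n_per_group = (
        {str(k): int(v) for k, v in coded.value_counts().items()}
        if mapping is not None or coded.nunique() == 2
        else {}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError:
        return HazardEstimate(
            hr=np.nan,
            ci95=(0.0, np.inf),
            p=np.nan,
            n_per_group=n_per_group,
            n_events=int(fit_df[event_col].sum()),
            flagged=True,
        )
    s = cph.summary.loc[covariate]
    flagged = bool(abs(s["coef"]) > 10)  # |log HR| > 10: effectively separated
    return HazardEstimate(
        hr=float(np.exp(s["coef"])),
        ci95=(
            (0.0, np.inf)
            if flagged
            else (float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"])))
        ),
        p=float(s["p"]),
        n_per_group=n_per_group,
        n_events=int(fit_df[event_col].sum()),
        flagged=flagged,
    )


def subgroup_analysis(
    df: pd.DataFrame,
    stratifier: str,
    arm_col: str = "arm",
    duration_col: str = "time_months",
    event_col: str = "event",
    treated=None,
) -> pd.DataFrame:
    """Per-stratum Cox HR of the treatment arm (forest-table layout).

    One row per level of ``stratifier``: n, events, HR of ``treated`` versus
    the reference arm, 95% CI and p.  Empty or single-arm strata are omitted
    with a warning.
    """
    rows = []
    for stratum, sub in df.groupby(stratifier, observed=True, sort=True):
        if sub.empty or sub[arm_col].nunique() < 2 or sub[event_col].sum() == 0:
            warnings.warn(f"stratum {stratum!r} not estimable; omitted")
            continue
        est = cox_hr(sub, arm_col, duration_col, event_col, positive=treated)
        rows.append(
            {
                "stratum": stratum,
                "n": len(sub),
                "n_events": est.n_events,
                "hr": est.hr,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
                "p": est.p,
                "flagged": est.flagged,
            }
        )
    return pd.DataFrame(rows)


def hazard_screen(
    expression: pd.DataFrame,
    records: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Median-split hazard screen over an expression matrix.

    For each gene (column of ``expression``, rows matched to ``records``):
    dichotomize at the median and fit a univariable Cox model, giving the HR
    of high versus low expressors.  Constant genes are skipped with a
    warning.  Output is sorted by HR ascending (most protective first).
    """
    if len(expression) != len(records):
        raise ValueError("expression rows must match cohort records")
    rows = []
    for gene in expression.columns:
        vals = expression[gene].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(f"gene {gene!r} is constant; skipped")
            continue
        df = records[[duration_col, event_col]].copy()
        df["high"] = median_split(vals)
        est = cox_hr(df, "high", duration_col, event_col)
        rows.append(
            {
                "gene": gene,
                "hr": est.hr,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
                "p": est.p,
                "n_high": est.n_per_group.get("1", est.n_per_group.get("True", 0)),
                "flagged": est.flagged,
            }
        )
    return pd.DataFrame(rows).sort_values("hr", kind="stable").reset_index(drop=True)
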
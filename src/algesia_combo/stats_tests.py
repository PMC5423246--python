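"""Per-day and time-course significance tests for the behavioral battery.

Two complementary schemes are provided:

* a mixed two-way ANOVA (treatment arm between animals, day repeated within
  animal) with Bonferroni-adjusted per-day arm-vs-control t contrasts, for
  the time-course comparison; and
* a per-day nonparametric scheme: Kruskal-Wallis omnibus across arms,
  followed (when the omnibus rejects) by pairwise Mann-Whitney U tests of
  each arm against the control, exact for small samples (n <= 8 per arm,
  no ties) and normal-approximated with midrank tie correction otherwise.

Behavioral endpoints at desk-scale n (6/arm) are short ordinal-ish scales
with censoring, hence the nonparametric per-day option alongside the
parametric time-course model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ExclusionWarning

__all__ = [
    "TestResult",
    "rm_anova_timecourse",
    "per_day_nonparametric",
    "results_frame",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test row (omnibus effect or post-hoc contrast)."""

    test_name: str
    assay: str
    grouping: str  # e.g. "arm", "day", "arm x day", "Ami 3 vs CCI+NS @ day 5"
    statistic: float
    df: str
    p_value: float
    adjusted_p: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise AnalysisError(f"p-value out of [0,1]: {self.p_value}")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise AnalysisError("Bonferroni-adjusted p below raw p")


def _complete_cases(
    records: pd.DataFrame, assay: str, arms: list[str]
) -> pd.DataFrame:
    sub = records[
        (records["assay"] == assay) & records["arm_label"].isin(arms)
    ].copy()
    days = sorted(sub["day"].unique())
    counts = sub.groupby("animal_id")["day"].nunique()
    incomplete = counts[counts < len(days)].index
    if len(incomplete):
        warnings.warn(
            f"dropping incomplete animal(s) for repeated-measures ANOVA: "
            f"{sorted(incomplete)}",
            ExclusionWarning,
            stacklevel=3,
        )
        sub = sub[~sub["animal_id"].isin(incomplete)]
    return sub


def rm_anova_timecourse(
    records: pd.DataFrame,
    assay: str,
    arms: list[str],
    control_arm: str,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Mixed arm x day ANOVA plus Bonferroni per-day contrasts vs control.

    Animals missing any day are dropped (complete-case) with a warning.
    The post-hoc family is each non-control arm vs the control at each day;
    the Bonferroni multiplier m is the size of that family.
    """
    if len(arms) < 2:
        raise AnalysisError("need >= 2 arms for the arm x day ANOVA")
    if control_arm not in arms:
        raise AnalysisError(f"control arm {control_arm!r} not among arms")
    sub = _complete_cases(records, assay, arms)
    days = sorted(sub["day"].unique())
    if len(days) < 2:
        raise AnalysisError("need >= 2 days (no repeated factor otherwise)")
    per_arm = sub.groupby("arm_label")["animal_id"].nunique()
    lacking = [a for a in arms if per_arm.get(a, 0) < 2]
    if lacking:
        raise AnalysisError(
            f"fewer than 2 complete animals in arm(s): {lacking}"
        )

    import pingouin as pg  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=sub,
            dv="value",
            within="day",
            subject="animal_id",
            between="arm_label",
        )
    name_map = {"arm_label": "arm", "day": "day", "Interaction": "arm x day"}
    results = [
        TestResult(
            test_name="mixed_anova",
            assay=assay,
            grouping=name_map.get(row["Source"], row["Source"]),
            statistic=float(row["F"]),
            df=f"{row['DF1']:g},{row['DF2']:g}",
            p_value=float(row.get("p_unc", row.get("p-unc"))),
        )
        for _, row in aov.iterrows()
    ]

    contrast_arms = [a for a in arms if a != control_arm]
    m = len(contrast_arms) * len(days)
    for day in days:
        ctrl = sub[
            (sub["arm_label"] == control_arm) & (sub["day"] == day)
        ]["value"].to_numpy()
        for arm in contrast_arms:
            vals = sub[
                (sub["arm_label"] == arm) & (sub["day"] == day)
            ]["value"].to_numpy()
            t, p = stats.ttest_ind(vals, ctrl)
            results.append(
                TestResult(
                    test_name="bonferroni_t",
                    assay=assay,
                    grouping=f"{arm} vs {control_arm} @ day {day:g}",
                    statistic=float(t),
                    df=f"{len(vals) + len(ctrl) - 2}",
                    p_value=float(p),
                    adjusted_p=float(min(1.0, m * p)),
                    extras={"m": m, "alpha": alpha},
                )
            )
    return results


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U; exact for n<=8 without ties, else midrank
    normal approximation."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def per_day_nonparametric(
    records: pd.DataFrame,
    assay: str,
    day: float,
    arms: list[str],
    control_arm: str,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Kruskal-Wallis across arms at one day, Mann-Whitney follow-up vs control.

    Pairwise contrasts run only when the omnibus p < alpha, and are
    Bonferroni-adjusted across the (n_arms - 1) contrasts.  All-identical
    values yield H=0, p=1 rather than an error.
    """
    if len(arms) < 2:
        raise AnalysisError("need >= 2 arms")
    if control_arm not in arms:
        raise AnalysisError(f"control arm {control_arm!r} not among arms")
    sub = records[
        (records["assay"] == assay)
        & (records["day"] == day)
        & records["arm_label"].isin(arms)
    ]
    groups = {
        arm: sub[sub["arm_label"] == arm]["value"].to_numpy() for arm in arms
    }
    lacking = [a for a, v in groups.items() if len(v) < 2]
    if lacking:
        raise AnalysisError(
            f"fewer than 2 animals at day {day:g} in arm(s): {lacking}"
        )
    values = list(groups.values())
    if np.all(np.concatenate(values) == values[0][0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values)
    results = [
        TestResult(
            test_name="kruskal_wallis",
            assay=assay,
            grouping=f"day {day:g}: {len(arms)} arms",
            statistic=float(h),
            df=f"{len(arms) - 1}",
            p_value=float(p),
        )
    ]
    if p < alpha:
        contrast_arms = [a for a in arms if a != control_arm]
        m = len(contrast_arms)
        for arm in contrast_arms:
            u, pu, method = _mannwhitney(groups[arm], groups[control_arm])
            results.append(
                TestResult(
                    test_name=f"mann_whitney_{method}",
                    assay=assay,
                    grouping=f"{arm} vs {control_arm} @ day {day:g}",
                    statistic=u,
                    df=f"{len(groups[arm])},{len(groups[control_arm])}",
                    p_value=pu,
                    adjusted_p=float(min(1.0, m * pu)),
                    extras={"m": m, "alpha": alpha},
                )
            )
    return results


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Test results as a tidy DataFrame (CSV-ready; ``extras`` dropped)."""
    rows = [
        {k: v for k, v in r.__dict__.items() if k != "extras"} for r in results
    ]
    return pd.DataFrame(rows)
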
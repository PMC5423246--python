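"""Additive-expectation combination analysis and interaction classification.

For a two-drug combination arm the null expectation is *effect additivity*:
the expected combination effect is the sum of the two mono-therapy effects
(on whichever statistic the assay uses — raw AUC, PI, or %MPE), with the
expected SEM propagated from the independent mono arms as
``sqrt(sem_A**2 + sem_B**2)``.

The observed combination effect is compared with this expectation by a
Welch-style two-sample t-test: the expected value is treated as an
independent estimate with its own standard error and Welch-Satterthwaite
degrees of freedom derived from the two mono arms, rather than as a known
constant (which would overstate significance).  For the normalized
statistics (PI, %MPE) the reference-arm means (vehicle, sham) enter every
score; their sampling error does not cancel in the observed-minus-expected
contrast, so the test additionally propagates it to first order
(delta method).  Without that term the test is measurably anticonservative
at n = 6 (the reference uncertainty inflates the contrast variance by about
a third).  The *reported* expected SEM stays ``sqrt(sem_A**2 + sem_B**2)``,
the conventional independent-arm propagation shown in summary tables.

Classification is significance-gated and three-way:

* ``potentiated``   — observed mean > expected mean and p < alpha,
* ``sub_additive``  — observed mean < expected mean and p < alpha,
* ``additive``      — otherwise (not significantly different).

``rule="raw"`` instead labels by the sign of (observed - expected) alone,
with no significance gate, calling only an exact tie additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ValidationError
from .io_model import ArmRoleMap
from .metrics import (
    STAT_BY_ASSAY,
    AUCSummary,
    arm_auc,
    percent_inhibition,
    percent_mpe,
)

__all__ = [
    "ExpectedEffect",
    "InteractionResult",
    "expected_additive",
    "compare_observed_expected",
    "reference_variance_components",
    "classify",
    "interaction_table",
    "CLASSIFICATIONS",
]

CLASSIFICATIONS = ("potentiated", "additive", "sub_additive")


class ExpectedEffect(NamedTuple):
    """Additive expectation: mean, propagated SEM, and effective df."""

    mean: float
    sem: float
    df: float


@dataclass(frozen=True)
class InteractionResult:
    """Observed-vs-expected comparison for one combination arm x assay."""

    combo_arm: str
    assay: str
    statistic: str
    observed_mean: float
    observed_sem: float
    n_observed: int
    expected_mean: float
    expected_sem: float
    t_statistic: float
    p_value: float
    classification: str
    alpha: float = 0.05


def _welch_satterthwaite(variances, dfs) -> float:
    num = sum(variances) ** 2
    den = sum(
        (v**2 / d) for v, d in zip(variances, dfs) if v > 0 and d > 0
    )
    if num == 0 or den == 0:
        return float("inf")
    return float(num / den)


def expected_additive(score_a: AUCSummary, score_b: AUCSummary) -> ExpectedEffect:
    """Sum of two mono-therapy effects with independent error propagation."""
    if score_a.assay != score_b.assay:
        raise AnalysisError(
            f"assay mismatch: {score_a.assay} vs {score_b.assay}"
        )
    if score_a.statistic != score_b.statistic:
        raise AnalysisError(
            f"statistic mismatch: {score_a.statistic} vs {score_b.statistic}"
        )
    mean = score_a.mean + score_b.mean
    sem = float(np.hypot(score_a.sem, score_b.sem))
    df = _welch_satterthwaite(
        (score_a.sem**2, score_b.sem**2), (score_a.n - 1, score_b.n - 1)
    )
    return ExpectedEffect(mean=mean, sem=sem, df=df)


def compare_observed_expected(
    combo: AUCSummary,
    expected: ExpectedEffect,
    reference_components: tuple[tuple[float, float], ...] = (),
) -> tuple[float, float]:
    """Welch t-test of the combination's per-animal effects vs the expectation.

    ``reference_components`` are optional extra ``(variance, df)`` terms for
    reference-arm means (vehicle/sham) whose sampling error enters the
    observed-minus-expected contrast of a normalized statistic; they are
    added to the squared standard error and to the Welch-Satterthwaite
    pooling.  Returns ``(t, p)`` two-sided.  Degenerate variance handling:
    if the total standard error is zero the result is p=1 for equal means
    and p=0 otherwise.
    """
    if combo.n < 2:
        raise AnalysisError("combination arm needs >= 2 animals")
    diff = combo.mean - expected.mean
    variances = [combo.sem**2, expected.sem**2]
    dfs = [combo.n - 1, expected.df]
    for var, df_ref in reference_components:
        variances.append(var)
        dfs.append(df_ref)
    se = float(np.sqrt(sum(variances)))
    if se == 0:
        return (0.0, 1.0) if diff == 0 else (float(np.inf) * np.sign(diff), 0.0)
    df = _welch_satterthwaite(variances, dfs)
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(df) else float(
        2.0 * stats.norm.sf(abs(t))
    )
    return float(t), p


def reference_variance_components(
    statistic: str,
    contrast: float,
    vehicle: AUCSummary,
    sham: AUCSummary | None = None,
) -> tuple[tuple[float, float], ...]:
    """First-order variance of the reference means in an obs-vs-expected
    contrast.

    ``contrast`` is the observed-minus-expected difference on the score
    scale.  For PI the vehicle mean enters each score; the net gradient of
    the contrast with respect to it is ``(contrast + 100) / AUC_vehicle``.
    For %MPE the gradients with respect to the vehicle and sham means are
    ``(100 + contrast) / span`` and ``-contrast / span`` with
    ``span = AUC_sham - AUC_vehicle``.  Raw AUC needs no adjustment.
    """
    if statistic == "raw_auc":
        return ()
    if statistic == "percent_inhibition":
        g_v = (contrast + 100.0) / vehicle.mean
        return (((g_v * vehicle.sem) ** 2, vehicle.n - 1),)
    if statistic == "percent_mpe":
        if sham is None:
            raise AnalysisError("%MPE reference adjustment requires the sham arm")
        span = sham.mean - vehicle.mean
        g_v = (100.0 + contrast) / span
        g_s = -contrast / span
        return (
            ((g_v * vehicle.sem) ** 2, vehicle.n - 1),
            ((g_s * sham.sem) ** 2, sham.n - 1),
        )
    raise AnalysisError(f"unknown statistic {statistic!r}")


def classify(
    observed_mean: float,
    expected_mean: float,
    p_value: float,
    alpha: float = 0.05,
    rule: str = "gated",
) -> str:
    """Three-way interaction label from the observed-vs-expected comparison."""
    if rule not in ("gated", "raw"):
        raise ValidationError(f"unknown label rule {rule!r}")
    if rule == "raw":
        if observed_mean > expected_mean:
            return "potentiated"
        if observed_mean < expected_mean:
            return "sub_additive"
        return "additive"
    if p_value < alpha and observed_mean > expected_mean:
        return "potentiated"
    if p_value < alpha and observed_mean < expected_mean:
        return "sub_additive"
    return "additive"


def _scored_summary(
    records: pd.DataFrame,
    arm: str,
    assay: str,
    vehicle: AUCSummary,
    sham: AUCSummary | None,
) -> AUCSummary:
    summary = arm_auc(records, arm, assay)
    stat = STAT_BY_ASSAY[assay]
    if stat == "percent_inhibition":
        return percent_inhibition(summary, vehicle)
    if stat == "percent_mpe":
        return percent_mpe(summary, vehicle, sham)
    return summary


def interaction_table(
    records: pd.DataFrame,
    role_map: ArmRoleMap,
    alpha: float = 0.05,
    rule: str = "gated",
    statistics: dict[str, str] | None = None,
) -> list[InteractionResult]:
    """One :class:`InteractionResult` per combination arm x assay.

    The statistic per assay defaults to the battery convention (raw AUC for
    von Frey, PI for acetone, %MPE for radiant heat).  Rows are ordered by
    role-map combination order, then assay name.
    """
    role_map.validate_against(records)
    stats_map = dict(STAT_BY_ASSAY)
    if statistics:
        stats_map.update(statistics)
    results = []
    assays = sorted(records["assay"].unique())
    for assay in assays:
        vehicle = arm_auc(records, role_map.vehicle_arm, assay)
        sham = (
            arm_auc(records, role_map.sham_arm, assay)
            if stats_map[assay] == "percent_mpe"
            else None
        )
        for combo, comp_a, comp_b in role_map.combinations:
            obs = _scored_summary(records, combo, assay, vehicle, sham)
            a = _scored_summary(records, comp_a, assay, vehicle, sham)
            b = _scored_summary(records, comp_b, assay, vehicle, sham)
            expected = expected_additive(a, b)
            refs = reference_variance_components(
                stats_map[assay], obs.mean - expected.mean, vehicle, sham
            )
            t, p = compare_observed_expected(obs, expected, refs)
            results.append(
                InteractionResult(
                    combo_arm=combo,
                    assay=assay,
                    statistic=obs.statistic,
                    observed_mean=obs.mean,
                    observed_sem=obs.sem,
                    n_observed=obs.n,
                    expected_mean=expected.mean,
                    expected_sem=expected.sem,
                    t_statistic=t,
                    p_value=p,
                    classification=classify(
                        obs.mean, expected.mean, p, alpha=alpha, rule=rule
                    ),
                    alpha=alpha,
                )
            )
    # deterministic order: combination order as declared, then assay
    order = {c[0]: i for i, c in enumerate(role_map.combinations)}
    results.sort(key=lambda r: (order[r.combo_arm], r.assay))
    return results


def interaction_frame(results: list[InteractionResult]) -> pd.DataFrame:
    """Interaction results as a tidy DataFrame (CSV-ready)."""
    if not results:
        raise AnalysisError("no interaction results to tabulate")
    return pd.DataFrame([r.__dict__ for r in results])


__all__.append("interaction_frame")
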
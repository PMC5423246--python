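"""Effect summaries: trapezoidal AUC, percent inhibition, and %MPE.

The whole antinociceptive effect of a treatment over the observation window
is summarized per animal as the area under its behavioral time course,
computed by the trapezoidal rule over the observed days (day 0 included).
Group effects are the mean +/- SEM of the per-animal AUCs, in
assay-unit x days ("a.u.").

Two normalized statistics are derived from the AUCs:

* percent inhibition (PI), for the acetone cold-allodynia count:
  ``PI_i = 100 * (AUC_vehicle - AUC_i) / AUC_vehicle``
* percent of maximum possible effect (%MPE), for the radiant-heat latency:
  ``MPE_i = 100 * (AUC_i - AUC_vehicle) / (AUC_sham - AUC_vehicle)``

Both use the *arm-level mean* AUC of the reference arms as constants, so the
per-animal scores are affine in the animal's own AUC and the group mean
score equals the score of the group mean AUC.  By construction the vehicle
arm scores 0 on both scales and the sham arm scores 100 on the %MPE scale.
Scores are not clamped: a worsening animal has negative PI, and an animal
better than sham exceeds 100 %MPE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_model import TimeCourse, to_timecourses

__all__ = [
    "AUCSummary",
    "EffectScore",
    "trapezoid_auc",
    "arm_auc",
    "percent_inhibition",
    "percent_mpe",
    "effect_table",
    "STAT_BY_ASSAY",
]

#: statistic conventionally used for each assay
STAT_BY_ASSAY = {
    "von_frey": "raw_auc",
    "acetone": "percent_inhibition",
    "radiant_heat": "percent_mpe",
}


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


@dataclass(frozen=True)
class AUCSummary:
    """Per-arm AUC summary with the per-animal AUCs retained."""

    arm_label: str
    assay: str
    per_animal: tuple[float, ...]
    statistic: str = "raw_auc"

    def __post_init__(self):
        if len(self.per_animal) < 2:
            raise AnalysisError(
                f"{self.arm_label}/{self.assay}: need >= 2 animals, "
                f"got {len(self.per_animal)}"
            )

    @property
    def n(self) -> int:
        return len(self.per_animal)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_animal))

    @property
    def sem(self) -> float:
        return _sem(np.asarray(self.per_animal))


@dataclass(frozen=True)
class EffectScore(AUCSummary):
    """A normalized per-arm effect statistic (PI or %MPE), same layout."""

    statistic: str = "percent_inhibition"


def trapezoid_auc(tc: TimeCourse) -> float:
    """Area under one time course by the trapezoidal rule (uneven spacing ok)."""
    return float(np.trapezoid(tc.values, tc.days))


def arm_auc(
    records: pd.DataFrame,
    arm_label: str,
    assay: str,
    scheduled_days: tuple[float, ...] | None = None,
) -> AUCSummary:
    """Per-animal trapezoidal AUCs for one arm x assay, with mean +/- SEM."""
    sub = records[records["arm_label"] == arm_label]
    if sub.empty:
        raise AnalysisError(f"arm {arm_label!r} not present in dataset")
    courses = to_timecourses(sub, assay, scheduled_days=scheduled_days)
    if len(courses) < 2:
        raise AnalysisError(
            f"{arm_label}/{assay}: need >= 2 animals with >= 2 observations"
        )
    return AUCSummary(
        arm_label=arm_label,
        assay=assay,
        per_animal=tuple(trapezoid_auc(tc) for tc in courses),
    )


def percent_inhibition(arm: AUCSummary, vehicle: AUCSummary) -> EffectScore:
    """Percent inhibition of each animal's AUC relative to the vehicle mean."""
    if arm.assay != vehicle.assay:
        raise AnalysisError(
            f"assay mismatch: {arm.assay} vs {vehicle.assay}"
        )
    denom = vehicle.mean
    if denom <= 0:
        raise AnalysisError(
            "percent inhibition undefined: vehicle mean AUC must be > 0, "
            f"got {denom:g}"
        )
    scores = tuple(100.0 * (denom - a) / denom for a in arm.per_animal)
    return EffectScore(
        arm_label=arm.arm_label,
        assay=arm.assay,
        per_animal=scores,
        statistic="percent_inhibition",
    )


def percent_mpe(
    arm: AUCSummary, vehicle: AUCSummary, sham: AUCSummary
) -> EffectScore:
    """Percent of the maximum possible effect (vehicle -> sham span)."""
    if len({arm.assay, vehicle.assay, sham.assay}) != 1:
        raise AnalysisError("assay mismatch between arm, vehicle and sham")
    span = sham.mean - vehicle.mean
    if span == 0:
        raise AnalysisError(
            "%MPE undefined: sham and vehicle mean AUCs are equal"
        )
    scores = tuple(
        100.0 * (a - vehicle.mean) / span for a in arm.per_animal
    )
    return EffectScore(
        arm_label=arm.arm_label,
        assay=arm.assay,
        per_animal=scores,
        statistic="percent_mpe",
    )


def effect_table(
    records: pd.DataFrame,
    vehicle_arm: str,
    sham_arm: str,
    arms: list[str] | None = None,
) -> pd.DataFrame:
    """Arm x assay effect summaries as a tidy table.

    Columns: ``arm_label, assay, statistic, n, mean, sem``; raw AUC for
    von Frey, PI for acetone, %MPE for radiant heat.  Rows sorted by
    (assay, arm).
    """
    if arms is None:
        arms = sorted(records["arm_label"].unique())
    rows = []
    for assay in sorted(records["assay"].unique()):
        stat = STAT_BY_ASSAY[assay]
        vehicle = arm_auc(records, vehicle_arm, assay)
        sham = arm_auc(records, sham_arm, assay) if stat == "percent_mpe" else None
        for arm in arms:
            summary = arm_auc(records, arm, assay)
            if stat == "percent_inhibition":
                summary = percent_inhibition(summary, vehicle)
            elif stat == "percent_mpe":
                summary = percent_mpe(summary, vehicle, sham)
            rows.append(
                {
                    "arm_label": arm,
                    "assay": assay,
                    "statistic": summary.statistic,
                    "n": summary.n,
                    "mean": summary.mean,
                    "sem": summary.sem,
                }
            )
    return pd.DataFrame(rows).sort_values(["assay", "arm_label"], ignore_index=True)
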
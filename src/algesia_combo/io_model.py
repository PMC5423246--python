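"""Tabular data model: read, validate and write behavioral datasets.

The canonical on-disk form is a long-format CSV with header
``animal_id,arm_label,assay,day,value`` — one row per animal x assay x day.
In memory the dataset is a :class:`pandas.DataFrame` with those columns.
Validation enforces the schema invariants (known assay, value within
``[0, cutoff]``, integer acetone counts, unique ``(animal_id, assay, day)``)
and reports offending 1-based data-row numbers.

Arm roles (which arm is the vehicle control, which the sham, and which
combination arm pairs with which two mono-therapy arms) are carried in a
small YAML sidecar rather than parsed out of labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .assays import ASSAYS, ASSAY_NAMES
from .errors import (
    DatasetError,
    DuplicateRecordError,
    ExclusionWarning,
    MissingColumnError,
    OutOfRangeError,
    UnknownAssayError,
    ValidationError,
)

__all__ = [
    "COLUMNS",
    "TimeCourse",
    "ArmRoleMap",
    "read_dataset",
    "write_dataset",
    "validate_records",
    "to_timecourses",
]

COLUMNS = ("animal_id", "arm_label", "assay", "day", "value")


@dataclass(frozen=True)
class TimeCourse:
    """Ordered (day, value) series for one animal x assay."""

    animal_id: str
    arm_label: str
    assay: str
    days: tuple[float, ...]
    values: tuple[float, ...]
    complete: bool = True  # False if a scheduled day is missing

    def __post_init__(self):
        if len(self.days) != len(self.values):
            raise ValidationError("days and values must be the same length")
        if len(self.days) < 2:
            raise ValidationError(
                f"{self.animal_id}/{self.assay}: need >= 2 points for an AUC"
            )
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError(
                f"{self.animal_id}/{self.assay}: days must be strictly increasing"
            )


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format behavioral table; returns a clean copy.

    Row numbers in error messages are 1-based positions in the input
    (matching data rows of a CSV written with a single header line).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
    out = df.loc[:, list(COLUMNS)].copy()
    out["animal_id"] = out["animal_id"].astype(str)
    out["arm_label"] = out["arm_label"].astype(str)
    out["assay"] = out["assay"].astype(str)
    rownum = np.arange(1, len(out) + 1)

    bad = ~out["assay"].isin(ASSAY_NAMES)
    if bad.any():
        names = sorted(out.loc[bad, "assay"].unique())
        raise UnknownAssayError(
            f"unknown assay value(s) {names}", rows=list(rownum[bad.to_numpy()])
        )
    try:
        out["day"] = pd.to_numeric(out["day"])
        out["value"] = pd.to_numeric(out["value"])
    except (ValueError, TypeError) as exc:
        raise DatasetError(f"non-numeric day or value: {exc}") from exc
    if (out["day"] < 0).any():
        rows = list(rownum[(out["day"] < 0).to_numpy()])
        raise OutOfRangeError("negative day", rows=rows)

    for name, spec in ASSAYS.items():
        sel = (out["assay"] == name).to_numpy()
        vals = out.loc[sel, "value"].to_numpy()
        bad_range = (vals < 0) | (vals > spec.cutoff)
        if spec.integer_valued:
            bad_range |= vals != np.rint(vals)
        if bad_range.any():
            raise OutOfRangeError(
                f"{name} values outside [0, {spec.cutoff:g}]"
                + (" or non-integer" if spec.integer_valued else ""),
                rows=list(rownum[sel][bad_range]),
            )

    dup = out.duplicated(subset=["animal_id", "assay", "day"], keep=False)
    if dup.any():
        keys = out.loc[dup, ["animal_id", "assay", "day"]].drop_duplicates()
        raise DuplicateRecordError(
            "duplicate (animal_id, assay, day): "
            + "; ".join(
                f"({r.animal_id}, {r.assay}, {r.day:g})" for r in keys.itertuples()
            ),
            rows=list(rownum[dup.to_numpy()]),
        )
    return out


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a behavioral CSV. Row order is irrelevant."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    return validate_records(df)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a validated dataset with deterministic row and column order."""
    out = validate_records(df).sort_values(
        ["arm_label", "animal_id", "assay", "day"], kind="mergesort"
    )
    out.to_csv(path, index=False)


def to_timecourses(
    records: pd.DataFrame,
    assay: str,
    scheduled_days: tuple[float, ...] | None = None,
) -> list[TimeCourse]:
    """One :class:`TimeCourse` per animal for ``assay``, days ascending.

    Animals with fewer than two observations are excluded with an
    :class:`ExclusionWarning`; animals missing a scheduled day are kept but
    flagged ``complete=False`` (also with a warning), never silently
    dropped.  Returned in sorted (arm, animal) order.
    """
    if assay not in ASSAY_NAMES:
        raise UnknownAssayError(f"unknown assay {assay!r}")
    sub = records[records["assay"] == assay]
    courses: list[TimeCourse] = []
    for (arm, animal), grp in sorted(
        sub.groupby(["arm_label", "animal_id"], sort=False),
        key=lambda kv: kv[0],
    ):
        grp = grp.sort_values("day")
        days = tuple(float(d) for d in grp["day"])
        if len(days) < 2:
            warnings.warn(
                f"excluding {animal} ({assay}): only {len(days)} observation(s)",
                ExclusionWarning,
                stacklevel=2,
            )
            continue
        complete = True
        if scheduled_days is not None:
            missed = sorted(set(scheduled_days) - set(days))
            if missed:
                complete = False
                warnings.warn(
                    f"{animal} ({assay}) missing scheduled day(s) {missed}",
                    ExclusionWarning,
                    stacklevel=2,
                )
        courses.append(
            TimeCourse(
                animal_id=animal,
                arm_label=arm,
                assay=assay,
                days=days,
                values=tuple(float(v) for v in grp["value"]),
                complete=complete,
            )
        )
    return courses


@dataclass
class ArmRoleMap:
    """Analysis roles of the arms: vehicle control, sham, combination triples.

    Each combination entry is ``(combo_arm, component_arm_A, component_arm_B)``
    where the components are the mono-therapy arms whose effects sum to the
    additive expectation for the combo.
    """

    vehicle_arm: str
    sham_arm: str
    combinations: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.combinations = [tuple(c) for c in self.combinations]
        for combo, a, b in self.combinations:
            if len({combo, a, b}) != 3:
                raise ValidationError(
                    f"combination {combo!r}: combo and component arms "
                    "must be three distinct labels"
                )

    def all_labels(self) -> set[str]:
        labels = {self.vehicle_arm, self.sham_arm}
        for triple in self.combinations:
            labels.update(triple)
        return labels

    def validate_against(self, records: pd.DataFrame) -> None:
        present = set(records["arm_label"].unique())
        missing = sorted(self.all_labels() - present)
        if missing:
            raise ValidationError(
                f"arm role map references arm(s) absent from dataset: {missing}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "vehicle_arm": self.vehicle_arm,
                    "sham_arm": self.sham_arm,
                    "combinations": [list(c) for c in self.combinations],
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "ArmRoleMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                vehicle_arm=raw["vehicle_arm"],
                sham_arm=raw["sham_arm"],
                combinations=[tuple(c) for c in raw.get("combinations", [])],
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed arm role map {path}: {exc}") from exc


def paperlike_role_map() -> ArmRoleMap:
    """Role map matching :func:`~algesia_combo.synthetic_data.default_paperlike_config`."""
    combos = []
    for short in ("Aq", "Eth"):
        for dose in (25, 50, 100):
            combos.append((f"Ami 3+{short} {dose}", "Ami 3", f"{short} {dose}"))
    return ArmRoleMap(vehicle_arm="CCI+NS", sham_arm="sham", combinations=combos)


__all__.append("paperlike_role_map")
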
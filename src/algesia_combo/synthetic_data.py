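"""Synthetic generator for CCI behavioral time courses.

The generator produces per-animal measurements for the three assays of the
neuropathic-pain battery (:mod:`algesia_combo.assays`) under a simple
pharmacodynamic model:

    value(day) = baseline + sign * amplitude * trajectory(day) * (1 - relief)

where ``baseline`` is the animal's pre-surgery response, ``sign`` and
``amplitude`` describe how far chronic constriction injury (CCI) moves the
response at full expression, ``trajectory(day)`` is the fraction of maximal
injury expressed on each measurement day (0 on day 0, rising to a plateau
within the first week), and ``relief`` is the fraction of the injury
component reversed by treatment.  Sham-operated animals have no injury
component, so drugs cannot move them — relief acts multiplicatively on the
injury, which keeps the maximum-possible-effect normalization interpretable.

Mono-therapy relief follows a saturating Emax dose-response,
``relief = Emax * dose / (dose + ED50)``.  A two-drug combination arm
combines its components' reliefs as

    relief = min(1, (relief_A + relief_B) * (1 + gamma))

so ``gamma = 0`` is exactly additive on the relief scale, ``gamma > 0``
potentiated, ``gamma < 0`` sub-additive.  The cap at 1 prevents
super-sham responses.

Gaussian noise is added per observation, values are censored at the assay
cutoff (and at 0 from below), and acetone responses are rounded to an
integer count in {0..5}.  A single global seed feeds one independent stream
per arm (keyed by arm index), so adding an arm never perturbs the data of
existing arms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .assays import ASSAYS, get_assay
from .errors import ConfigError

__all__ = [
    "DrugParams",
    "ArmSpec",
    "AssayParams",
    "SimulationConfig",
    "simulate_dataset",
    "default_paperlike_config",
    "mono_relief",
    "combination_relief",
]

DEFAULT_DAYS = (0.0, 3.0, 5.0, 7.0)
#: fraction of maximal injury expressed on each default day (plateau by day 7)
DEFAULT_TRAJECTORY = (0.0, 0.8, 0.95, 1.0)


@dataclass(frozen=True)
class DrugParams:
    """Saturating dose-response of one drug: Emax in [0,1], ED50 in mg/kg."""

    emax: float
    ed50: float


@dataclass(frozen=True)
class ArmSpec:
    """One experimental arm: surgery type, drug(s) with doses, group size."""

    label: str
    surgery: str  # "CCI" | "sham"
    drugs: tuple[tuple[str, float], ...] = ()
    n_animals: int = 6


@dataclass(frozen=True)
class AssayParams:
    """Per-assay generator parameters, all in the assay's own units."""

    baseline_mean: float
    baseline_sd: float
    injury_amplitude: float
    noise_sd: float


@dataclass
class SimulationConfig:
    """Full parameterization of one simulated study."""

    arms: list[ArmSpec]
    days: tuple[float, ...] = DEFAULT_DAYS
    assay_params: dict[str, AssayParams] = field(default_factory=dict)
    injury_trajectory: dict[str, tuple[float, ...]] = field(default_factory=dict)
    drug_params: dict[str, DrugParams] = field(default_factory=dict)
    interaction_gamma: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.arms = [
            a if isinstance(a, ArmSpec) else ArmSpec(**a) for a in self.arms
        ]
        self.days = tuple(float(d) for d in self.days)
        self.assay_params = {
            k: v if isinstance(v, AssayParams) else AssayParams(**v)
            for k, v in self.assay_params.items()
        }
        self.injury_trajectory = {
            k: tuple(float(x) for x in v) for k, v in self.injury_trajectory.items()
        }
        self.drug_params = {
            k: v if isinstance(v, DrugParams) else DrugParams(**v)
            for k, v in self.drug_params.items()
        }
        self.validate()

    def validate(self) -> None:
        if not self.arms:
            raise ConfigError("arms", "at least one arm is required")
        if len({a.label for a in self.arms}) != len(self.arms):
            raise ConfigError("arms", "arm labels must be unique")
        for arm in self.arms:
            if arm.surgery not in ("CCI", "sham"):
                raise ConfigError(
                    "arms.surgery", f"{arm.label!r}: must be 'CCI' or 'sham'"
                )
            if arm.surgery == "sham" and arm.drugs:
                raise ConfigError(
                    "arms.drugs", f"{arm.label!r}: sham arms must have no drugs"
                )
            if arm.n_animals < 2:
                raise ConfigError(
                    "arms.n_animals",
                    f"{arm.label!r}: need >= 2 animals for an SEM",
                )
            for drug, dose in arm.drugs:
                if drug not in self.drug_params:
                    raise ConfigError(
                        "drug_params", f"no dose-response parameters for {drug!r}"
                    )
                if dose <= 0:
                    raise ConfigError(
                        "arms.drugs", f"{arm.label!r}: dose for {drug!r} must be > 0"
                    )
        days = np.asarray(self.days, dtype=float)
        if len(days) < 2 or np.any(np.diff(days) <= 0):
            raise ConfigError("days", "must be strictly increasing with >= 2 entries")
        if days[0] != 0:
            raise ConfigError("days", "days[0] must be 0 (pre-surgery baseline)")
        if not self.assay_params:
            raise ConfigError("assay_params", "at least one assay is required")
        for name, params in self.assay_params.items():
            get_assay(name)  # raises on unknown assay
            if params.baseline_sd < 0 or params.noise_sd < 0:
                raise ConfigError(
                    f"assay_params.{name}", "baseline_sd and noise_sd must be >= 0"
                )
            if params.injury_amplitude < 0:
                raise ConfigError(
                    f"assay_params.{name}", "injury_amplitude must be >= 0"
                )
            traj = self.injury_trajectory.get(name)
            if traj is None:
                raise ConfigError(
                    f"injury_trajectory.{name}", "missing trajectory for assay"
                )
            t = np.asarray(traj, dtype=float)
            if len(t) != len(days):
                raise ConfigError(
                    f"injury_trajectory.{name}", "length must match days"
                )
            if t[0] != 0:
                raise ConfigError(
                    f"injury_trajectory.{name}", "value at day 0 must be 0"
                )
            if np.any(t < 0) or np.any(t > 1) or np.any(np.diff(t) < 0):
                raise ConfigError(
                    f"injury_trajectory.{name}",
                    "values must be in [0,1] and non-decreasing",
                )
        for drug, dp in self.drug_params.items():
            if not 0 <= dp.emax <= 1:
                raise ConfigError(f"drug_params.{drug}.emax", "must be in [0,1]")
            if dp.ed50 <= 0:
                raise ConfigError(f"drug_params.{drug}.ed50", "must be > 0")
        for label in self.interaction_gamma:
            if label not in {a.label for a in self.arms}:
                raise ConfigError(
                    "interaction_gamma", f"unknown arm label {label!r}"
                )

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arms"] = [
            {**a, "drugs": [list(x) for x in a["drugs"]]} for a in d["arms"]
        ]
        d["days"] = list(d["days"])
        d["injury_trajectory"] = {
            k: list(v) for k, v in d["injury_trajectory"].items()
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["arms"] = [
            ArmSpec(
                label=a["label"],
                surgery=a["surgery"],
                drugs=tuple((d, float(x)) for d, x in a.get("drugs", ())),
                n_animals=int(a.get("n_animals", 6)),
            )
            for a in raw["arms"]
        ]
        return cls(**raw)


def mono_relief(dose: float, params: DrugParams) -> float:
    """Fraction of injury reversed by one drug at ``dose`` (Emax model)."""
    return params.emax * dose / (dose + params.ed50)


def combination_relief(reliefs: list[float], gamma: float) -> float:
    """Combined relief: additive on the relief scale, scaled by (1+gamma)."""
    return float(min(1.0, max(0.0, sum(reliefs) * (1.0 + gamma))))


def _arm_relief(arm: ArmSpec, config: SimulationConfig) -> float:
    if not arm.drugs:
        return 0.0
    parts = [mono_relief(dose, config.drug_params[d]) for d, dose in arm.drugs]
    if len(parts) == 1:
        return float(min(1.0, parts[0]))
    gamma = config.interaction_gamma.get(arm.label, 0.0)
    return combination_relief(parts, gamma)


def simulate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one study; returns the long-format behavioral table.

    Columns: ``animal_id, arm_label, assay, day, value``.  The same config
    and seed always yield an identical table.
    """
    config.validate()
    days = np.asarray(config.days, dtype=float)
    assay_names = sorted(config.assay_params)
    frames = []
    for arm_index, arm in enumerate(config.arms):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(arm_index,))
        )
        relief = _arm_relief(arm, config)
        injured = arm.surgery == "CCI"
        for j in range(arm.n_animals):
            animal = f"{arm.label}_r{j + 1}"
            for assay_name in assay_names:
                spec = ASSAYS[assay_name]
                p = config.assay_params[assay_name]
                traj = np.asarray(config.injury_trajectory[assay_name])
                baseline = rng.normal(p.baseline_mean, p.baseline_sd)
                noise = rng.normal(0.0, p.noise_sd, size=len(days))
                injury = (
                    spec.sign * p.injury_amplitude * traj * (1.0 - relief)
                    if injured
                    else 0.0
                )
                values = baseline + injury + noise
                values = np.clip(values, 0.0, spec.cutoff)
                if spec.integer_valued:
                    values = np.rint(values)
                frames.append(
                    pd.DataFrame(
                        {
                            "animal_id": animal,
                            "arm_label": arm.label,
                            "assay": assay_name,
                            "day": days,
                            "value": values,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


# -- the default study design ---------------------------------------------

AMI = "amitriptyline"
AQ = "aqueous_extract"
ETH = "ethanolic_extract"
GBP = "gabapentin"

VEHICLE_ARM = "CCI+NS"
SHAM_ARM = "sham"


def _combo_label(dose_a: float, drug_b: str, dose_b: float) -> str:
    short = {AQ: "Aq", ETH: "Eth"}[drug_b]
    return f"Ami {dose_a:g}+{short} {dose_b:g}"


def default_paperlike_config(
    seed: int = 0, include_positive_control: bool = False
) -> SimulationConfig:
    """Default study design: 17 arms of n=6, days {0,3,5,7}.

    Arms: sham; CCI+vehicle; amitriptyline 3/10/30 mg/kg; aqueous and
    ethanolic plant-extract series 25/50/100 mg/kg; and the six
    low-dose-amitriptyline (3 mg/kg) + extract combination arms.  Numeric
    defaults were tuned once so that group-level magnitudes (e.g. the
    vehicle-arm mechanical AUC of roughly 40-50 g x days) sit in the range
    reported for rat CCI studies, then frozen.  Combination arms with the
    two higher extract doses default to a positive interaction
    (``gamma > 0``); the 25 mg/kg combinations are additive.

    ``include_positive_control`` adds an optional gabapentin arm (100 mg/kg)
    as a conventional positive control.
    """
    arms = [
        ArmSpec(SHAM_ARM, "sham", (), 6),
        # vehicle receives saline only: modeled as CCI with no drugs
        ArmSpec(VEHICLE_ARM, "CCI", (), 6),
    ]
    for dose in (3, 10, 30):
        arms.append(ArmSpec(f"Ami {dose}", "CCI", ((AMI, float(dose)),), 6))
    for drug, short in ((AQ, "Aq"), (ETH, "Eth")):
        for dose in (25, 50, 100):
            arms.append(
                ArmSpec(f"{short} {dose}", "CCI", ((drug, float(dose)),), 6)
            )
    for drug in (AQ, ETH):
        for dose in (25, 50, 100):
            arms.append(
                ArmSpec(
                    _combo_label(3, drug, dose),
                    "CCI",
                    ((AMI, 3.0), (drug, float(dose))),
                    6,
                )
            )
    if include_positive_control:
        arms.append(ArmSpec("GBP 100", "CCI", ((GBP, 100.0),), 6))

    gamma = {
        _combo_label(3, AQ, 25): 0.0,
        _combo_label(3, AQ, 50): 0.4,
        _combo_label(3, AQ, 100): 0.6,
        _combo_label(3, ETH, 25): 0.0,
        _combo_label(3, ETH, 50): 0.4,
        _combo_label(3, ETH, 100): 0.5,
    }
    return SimulationConfig(
        arms=arms,
        days=DEFAULT_DAYS,
        assay_params={
            "von_frey": AssayParams(15.0, 1.2, 13.0, 1.0),
            "acetone": AssayParams(0.5, 0.3, 4.0, 0.6),
            "radiant_heat": AssayParams(12.0, 1.0, 7.0, 0.8),
        },
        injury_trajectory={name: DEFAULT_TRAJECTORY for name in ASSAYS},
        drug_params={
            AMI: DrugParams(emax=0.9, ed50=12.0),
            AQ: DrugParams(emax=0.85, ed50=140.0),
            ETH: DrugParams(emax=0.85, ed50=160.0),
            GBP: DrugParams(emax=0.9, ed50=60.0),
        },
        interaction_gamma=gamma,
        seed=seed,
    )
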
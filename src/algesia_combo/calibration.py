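"""Monte-Carlo calibration of the interaction classifier.

A minimal five-arm study (sham, CCI+vehicle, two mono-therapies, one
combination) is simulated repeatedly on the radiant-heat assay, analyzed on
the %MPE scale, and the interaction label recorded.  Two scenarios matter:

* ``gamma = 0`` — true additivity on the relief scale.  On %MPE the
  additive expectation then equals the true combination effect (the
  baseline-referenced statistics are exactly additive under the generator,
  absent censoring), so any non-additive label is a false positive and the
  rate of such labels measures the classifier's type-I error.
* large ``gamma`` — the true combination effect exceeds the additive
  prediction by a known margin; the potentiated-label rate measures power.

Scenario constants (frozen): radiant-heat baseline 12 s (between-animal SD
0.5 s), injury amplitude 7 s, observation noise SD 0.8 s, trajectory
(0, 0.8, 0.95, 1.0) over days (0, 3, 5, 7), each mono drug at a dose equal
to its ED50 with Emax 0.5 (relief 0.25 each), n = 6 per arm.  With these
numbers the strong-synergy scenario ``gamma = 0.9`` puts the true combined
relief at 0.95, i.e. a true %MPE of 95 vs an expected 50 — about 5-6
propagated SEMs above the additive prediction, comfortably beyond the
4-SEM margin used to define "detectable" synergy.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .interaction import (
    classify,
    compare_observed_expected,
    expected_additive,
    reference_variance_components,
)
from .metrics import arm_auc, percent_mpe
from .synthetic_data import (
    ArmSpec,
    AssayParams,
    DrugParams,
    SimulationConfig,
    simulate_dataset,
)

__all__ = ["calibration_config", "classification_rates"]

_DAYS = (0.0, 3.0, 5.0, 7.0)
_TRAJ = (0.0, 0.8, 0.95, 1.0)


def calibration_config(gamma: float, seed: int) -> SimulationConfig:
    """Five-arm radiant-heat scenario with combination interaction ``gamma``."""
    return SimulationConfig(
        arms=[
            ArmSpec("sham", "sham", (), 6),
            ArmSpec("vehicle", "CCI", (), 6),
            ArmSpec("monoA", "CCI", (("drugA", 30.0),), 6),
            ArmSpec("monoB", "CCI", (("drugB", 30.0),), 6),
            ArmSpec("combo", "CCI", (("drugA", 30.0), ("drugB", 30.0)), 6),
        ],
        days=_DAYS,
        assay_params={"radiant_heat": AssayParams(12.0, 0.5, 7.0, 0.8)},
        injury_trajectory={"radiant_heat": _TRAJ},
        drug_params={
            "drugA": DrugParams(emax=0.5, ed50=30.0),
            "drugB": DrugParams(emax=0.5, ed50=30.0),
        },
        interaction_gamma={"combo": gamma},
        seed=seed,
    )


def _classify_once(config: SimulationConfig, alpha: float) -> str:
    records = simulate_dataset(config)
    assay = "radiant_heat"
    vehicle = arm_auc(records, "vehicle", assay)
    sham = arm_auc(records, "sham", assay)
    obs = percent_mpe(arm_auc(records, "combo", assay), vehicle, sham)
    a = percent_mpe(arm_auc(records, "monoA", assay), vehicle, sham)
    b = percent_mpe(arm_auc(records, "monoB", assay), vehicle, sham)
    expected = expected_additive(a, b)
    refs = reference_variance_components(
        "percent_mpe", obs.mean - expected.mean, vehicle, sham
    )
    _, p = compare_observed_expected(obs, expected, refs)
    return classify(obs.mean, expected.mean, p, alpha=alpha)


def classification_rates(
    gamma: float,
    n_reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Label frequencies over ``n_reps`` replicate simulated studies.

    Returns a dict with the three label rates plus ``non_additive`` (the
    complement of the additive rate).  Replicate seeds are drawn from a
    child stream of ``seed`` and kept below 2**31.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_reps) % (2**31)
    labels = Counter(
        _classify_once(calibration_config(gamma, int(s)), alpha)
        for s in rep_seeds
    )
    rates = {k: labels.get(k, 0) / n_reps for k in ("potentiated", "additive", "sub_additive")}
    rates["non_additive"] = 1.0 - rates["additive"]
    return rates
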
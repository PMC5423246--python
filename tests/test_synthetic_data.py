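"""Generator invariants: determinism, censoring, dose monotonicity, additivity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from algesia_combo.errors import ConfigError
from algesia_combo.synthetic_data import (
    ArmSpec,
    AssayParams,
    DrugParams,
    SimulationConfig,
    default_paperlike_config,
    mono_relief,
    simulate_dataset,
)


def small_config(noise_sd=0.5, baseline_sd=0.5, gamma=0.0, seed=7, doses=(10.0, 10.0)):
    return SimulationConfig(
        arms=[
            ArmSpec("sham", "sham", (), 3),
            ArmSpec("veh", "CCI", (), 3),
            ArmSpec("A", "CCI", (("a", doses[0]),), 3),
            ArmSpec("B", "CCI", (("b", doses[1]),), 3),
            ArmSpec("AB", "CCI", (("a", doses[0]), ("b", doses[1])), 3),
        ],
        days=(0.0, 3.0, 5.0, 7.0),
        assay_params={
            "von_frey": AssayParams(15.0, baseline_sd, 13.0, noise_sd),
            "acetone": AssayParams(0.5, 0.2, 4.0, noise_sd),
            "radiant_heat": AssayParams(12.0, baseline_sd, 7.0, noise_sd),
        },
        injury_trajectory={
            a: (0.0, 0.8, 0.95, 1.0)
            for a in ("von_frey", "acetone", "radiant_heat")
        },
        drug_params={
            "a": DrugParams(0.6, 10.0),
            "b": DrugParams(0.6, 10.0),
        },
        interaction_gamma={"AB": gamma},
        seed=seed,
    )


def test_same_seed_gives_identical_tables():
    df1 = simulate_dataset(small_config(seed=11))
    df2 = simulate_dataset(small_config(seed=11))
    pd.testing.assert_frame_equal(df1, df2)


def test_different_seed_changes_values():
    df1 = simulate_dataset(small_config(seed=11))
    df2 = simulate_dataset(small_config(seed=12))
    assert not np.allclose(df1["value"], df2["value"])


def test_adding_an_arm_leaves_existing_arms_untouched():
    cfg = small_config(seed=3)
    extended = dataclasses.replace(
        cfg, arms=cfg.arms + [ArmSpec("extra", "CCI", (("a", 5.0),), 3)]
    )
    base = simulate_dataset(cfg)
    ext = simulate_dataset(extended)
    pd.testing.assert_frame_equal(
        base, ext[ext["arm_label"] != "extra"].reset_index(drop=True)
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_censoring_and_acetone_integrality(seed):
    df = simulate_dataset(small_config(noise_sd=5.0, seed=seed))
    vf = df[df["assay"] == "von_frey"]["value"]
    rh = df[df["assay"] == "radiant_heat"]["value"]
    ac = df[df["assay"] == "acetone"]["value"]
    assert vf.between(0, 60).all()
    assert rh.between(0, 30).all()
    assert ac.between(0, 5).all()
    assert (ac == np.rint(ac)).all()


def test_sham_values_equal_baseline_without_noise():
    cfg = small_config(noise_sd=0.0, baseline_sd=0.0)
    df = simulate_dataset(cfg)
    sham = df[(df["arm_label"] == "sham") & (df["assay"] == "von_frey")]
    assert np.allclose(sham["value"], 15.0)


def test_vehicle_follows_injury_trajectory_without_noise():
    cfg = small_config(noise_sd=0.0, baseline_sd=0.0)
    df = simulate_dataset(cfg)
    veh = df[(df["arm_label"] == "veh") & (df["assay"] == "radiant_heat")]
    expected = 12.0 - 7.0 * np.array([0.0, 0.8, 0.95, 1.0])
    animal = veh[veh["animal_id"] == veh["animal_id"].iloc[0]].sort_values("day")
    assert np.allclose(animal["value"], expected)


def test_relief_is_emax_over_two_at_ed50():
    assert mono_relief(10.0, DrugParams(emax=0.8, ed50=10.0)) == pytest.approx(0.4)


def test_higher_dose_never_worse_without_noise():
    """Monotone dose effect: more drug never moves the expected value toward
    the injured extreme, on any assay or day."""
    for dose_lo, dose_hi in [(5.0, 10.0), (10.0, 40.0)]:
        lo = simulate_dataset(
            small_config(noise_sd=0.0, baseline_sd=0.0, doses=(dose_lo, dose_lo))
        )
        hi = simulate_dataset(
            small_config(noise_sd=0.0, baseline_sd=0.0, doses=(dose_hi, dose_hi))
        )
        for assay, sign in [("von_frey", -1), ("acetone", +1), ("radiant_heat", -1)]:
            a_lo = lo[(lo["arm_label"] == "A") & (lo["assay"] == assay)]["value"]
            a_hi = hi[(hi["arm_label"] == "A") & (hi["assay"] == assay)]["value"]
            # injured direction is `sign`; higher dose moves against it
            assert np.all(sign * (a_hi.to_numpy() - a_lo.to_numpy()) <= 1e-9)


def test_additive_combination_matches_sum_of_reliefs_without_noise():
    """gamma=0: the combination's injury reduction equals the summed mono
    reduction exactly (no censoring in this regime)."""
    cfg = small_config(noise_sd=0.0, baseline_sd=0.0, gamma=0.0)
    df = simulate_dataset(cfg)
    rh = df[df["assay"] == "radiant_heat"]

    def day7(arm):
        sub = rh[(rh["arm_label"] == arm) & (rh["day"] == 7.0)]
        return sub["value"].iloc[0]

    relief = mono_relief(10.0, DrugParams(0.6, 10.0))  # 0.3 each
    assert day7("AB") == pytest.approx(12.0 - 7.0 * (1 - 2 * relief))
    # injury reduction of combo == sum of mono reductions
    assert (day7("AB") - day7("veh")) == pytest.approx(
        (day7("A") - day7("veh")) + (day7("B") - day7("veh"))
    )


@pytest.mark.parametrize(
    "mutation, field",
    [
        (dict(days=(0.0, 3.0, 3.0, 7.0)), "days"),
        (dict(days=(1.0, 3.0, 5.0, 7.0)), "days"),
        (dict(seed=0), None),  # control: valid
    ],
)
def test_invalid_days_rejected_naming_field(mutation, field):
    cfg = small_config()
    if field is None:
        dataclasses.replace(cfg, **mutation)
        return
    with pytest.raises(ConfigError, match=field):
        dataclasses.replace(cfg, **mutation)


def test_invalid_trajectory_and_drug_params_rejected():
    cfg = small_config()
    with pytest.raises(ConfigError, match="injury_trajectory"):
        dataclasses.replace(
            cfg,
            injury_trajectory={**cfg.injury_trajectory, "von_frey": (0.0, 0.9, 0.8, 1.0)},
        )
    with pytest.raises(ConfigError, match="emax"):
        dataclasses.replace(
            cfg, drug_params={**cfg.drug_params, "a": DrugParams(1.3, 10.0)}
        )
    with pytest.raises(ConfigError, match="n_animals"):
        dataclasses.replace(cfg, arms=[ArmSpec("solo", "CCI", (), 1)] + cfg.arms[1:])
    with pytest.raises(ConfigError, match="drugs"):
        dataclasses.replace(
            cfg, arms=[ArmSpec("sham", "sham", (("a", 1.0),), 3)] + cfg.arms[1:]
        )


def test_config_yaml_round_trip(tmp_path):
    cfg = small_config(gamma=0.25)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    loaded = SimulationConfig.from_yaml(path)
    pd.testing.assert_frame_equal(simulate_dataset(cfg), simulate_dataset(loaded))


class TestDefaultStudyDesign:
    def test_structure(self):
        cfg = default_paperlike_config(seed=0)
        assert len(cfg.arms) == 17
        assert all(a.n_animals == 6 for a in cfg.arms)
        assert cfg.days == (0.0, 3.0, 5.0, 7.0)
        labels = {a.label for a in cfg.arms}
        assert {"sham", "CCI+NS", "Ami 3", "Aq 100", "Eth 50", "Ami 3+Aq 100"} <= labels

    def test_two_calls_identical(self):
        assert default_paperlike_config(seed=4) == default_paperlike_config(seed=4)

    def test_positive_control_arm_optional(self):
        cfg = default_paperlike_config(seed=0, include_positive_control=True)
        assert len(cfg.arms) == 18
        assert any(a.label == "GBP 100" for a in cfg.arms)

    def test_assay_cutoffs(self):
        from algesia_combo.assays import ASSAYS

        assert ASSAYS["von_frey"].cutoff == 60.0
        assert ASSAYS["radiant_heat"].cutoff == 30.0
        assert ASSAYS["acetone"].cutoff == 5.0
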
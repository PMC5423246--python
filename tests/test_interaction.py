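"""Additive expectation, observed-vs-expected test, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from algesia_combo.errors import AnalysisError
from algesia_combo.interaction import (
    ExpectedEffect,
    classify,
    compare_observed_expected,
    expected_additive,
    interaction_frame,
    interaction_table,
)
from algesia_combo.metrics import AUCSummary


def summary(mean, sem, n=6, label="arm", assay="von_frey", statistic="raw_auc"):
    """Build a per-animal sample with exactly the requested mean and SEM."""
    base = np.linspace(-1.0, 1.0, n)
    base -= base.mean()
    if sem > 0:
        base *= sem * np.sqrt(n) / base.std(ddof=1)
    else:
        base[:] = 0.0
    return AUCSummary(label, assay, tuple(mean + base), statistic=statistic)


def test_expected_additive_sums_means_and_propagates_sems():
    a = summary(53.1, 5.0)
    b = summary(51.2, 5.2)
    exp = expected_additive(a, b)
    assert exp.mean == pytest.approx(104.3)
    assert exp.sem == pytest.approx(np.hypot(5.0, 5.2))


def test_expected_additive_symmetry():
    a, b = summary(10.0, 1.0), summary(20.0, 2.0)
    assert expected_additive(a, b) == expected_additive(b, a)


def test_expected_additive_zero_mean_component():
    a = summary(0.0, 1.5)
    b = summary(30.0, 2.0)
    exp = expected_additive(a, b)
    assert exp.mean == pytest.approx(30.0)
    assert exp.sem == pytest.approx(np.hypot(1.5, 2.0))


def test_expected_additive_rejects_mismatches():
    with pytest.raises(AnalysisError, match="assay"):
        expected_additive(summary(1, 1, assay="acetone"), summary(1, 1))
    with pytest.raises(AnalysisError, match="statistic"):
        expected_additive(
            summary(1, 1, statistic="percent_inhibition"), summary(1, 1)
        )


class TestCompareObservedExpected:
    def test_equal_means_give_t_zero_p_one(self):
        obs = summary(10.0, 0.0, n=4)
        t, p = compare_observed_expected(obs, ExpectedEffect(10.0, 0.5, 10.0))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_large_separation_is_highly_significant(self):
        # closed-form check: t = 10 / sqrt(0.1^2 + 0.1^2) ~ 70
        obs = summary(10.0, 0.1, n=6)
        t, p = compare_observed_expected(obs, ExpectedEffect(0.0, 0.1, 10.0))
        assert t == pytest.approx(10.0 / np.hypot(0.1, 0.1), rel=1e-6)
        assert p < 1e-3

    def test_degenerate_zero_variance(self):
        obs_equal = summary(5.0, 0.0, n=4)
        _, p = compare_observed_expected(obs_equal, ExpectedEffect(5.0, 0.0, 5.0))
        assert p == 1.0
        _, p = compare_observed_expected(obs_equal, ExpectedEffect(7.0, 0.0, 5.0))
        assert p == 0.0

    def test_welch_satterthwaite_df_matches_scipy_two_sample(self):
        """Cross-check against scipy's Welch test when the 'expected' side is
        literally another sample."""
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, 6)
        y = rng.normal(12, 3, 6)
        obs = AUCSummary("x", "von_frey", tuple(x))
        ys = AUCSummary("y", "von_frey", tuple(y))
        exp = ExpectedEffect(ys.mean, ys.sem, ys.n - 1)
        t, p = compare_observed_expected(obs, exp)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "obs, exp, p, label",
        [
            (46.0, 21.8, 0.004, "potentiated"),
            (62.1, 105.5, 0.001, "sub_additive"),
            (107.0, 105.1, 0.9, "additive"),  # higher but not significant
            (21.8, 21.8, 0.0, "additive"),  # equal means
        ],
    )
    def test_gated_rule(self, obs, exp, p, label):
        assert classify(obs, exp, p) == label

    def test_raw_rule_ignores_significance(self):
        assert classify(107.0, 105.1, 0.9, rule="raw") == "potentiated"
        assert classify(62.1, 105.5, 0.9, rule="raw") == "sub_additive"
        assert classify(50.0, 50.0, 0.9, rule="raw") == "additive"

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        obs=st.floats(-50, 150, allow_nan=False),
        shift=st.floats(0.001, 100, allow_nan=False),
        exp=st.floats(-50, 150, allow_nan=False),
        p=st.floats(0, 1, allow_nan=False),
        alpha=st.floats(0.001, 0.2, allow_nan=False),
    )
    def test_monotone_in_observed_mean(self, obs, shift, exp, p, alpha):
        """Raising the observed mean never moves the label toward
        sub-additive."""
        order = {"sub_additive": 0, "additive": 1, "potentiated": 2}
        lo = classify(obs, exp, p, alpha=alpha)
        hi = classify(obs + shift, exp, p, alpha=alpha)
        assert order[hi] >= order[lo]


class TestInteractionTable:
    def test_paperlike_dataset_yields_18_rows(self, paperlike_dataset, role_map):
        results = interaction_table(paperlike_dataset, role_map)
        assert len(results) == 18  # 6 combination arms x 3 assays
        assert {r.statistic for r in results} == {
            "raw_auc",
            "percent_inhibition",
            "percent_mpe",
        }

    def test_expected_mean_is_exact_component_sum(
        self, paperlike_dataset, role_map
    ):
        from algesia_combo.interaction import _scored_summary
        from algesia_combo.metrics import arm_auc

        results = interaction_table(paperlike_dataset, role_map)
        comp = {c[0]: (c[1], c[2]) for c in role_map.combinations}
        for r in results:
            vehicle = arm_auc(paperlike_dataset, role_map.vehicle_arm, r.assay)
            sham = arm_auc(paperlike_dataset, role_map.sham_arm, r.assay)
            a = _scored_summary(paperlike_dataset, comp[r.combo_arm][0], r.assay, vehicle, sham)
            b = _scored_summary(paperlike_dataset, comp[r.combo_arm][1], r.assay, vehicle, sham)
            assert r.expected_mean == a.mean + b.mean  # exact, machine precision

    def test_strong_synergy_low_noise_is_labeled_potentiated(self):
        from algesia_combo.calibration import calibration_config
        from algesia_combo.io_model import ArmRoleMap
        from algesia_combo.synthetic_data import simulate_dataset
        import dataclasses

        cfg = calibration_config(gamma=0.9, seed=123)
        cfg = dataclasses.replace(
            cfg,
            assay_params={
                "radiant_heat": dataclasses.replace(
                    cfg.assay_params["radiant_heat"], noise_sd=0.2, baseline_sd=0.1
                )
            },
        )
        rm = ArmRoleMap("vehicle", "sham", [("combo", "monoA", "monoB")])
        (r,) = interaction_table(simulate_dataset(cfg), rm)
        assert r.classification == "potentiated"

    def test_deterministic_row_order(self, paperlike_dataset, role_map):
        r1 = interaction_table(paperlike_dataset, role_map)
        r2 = interaction_table(paperlike_dataset, role_map)
        assert [(r.combo_arm, r.assay) for r in r1] == [
            (r.combo_arm, r.assay) for r in r2
        ]
        combos = [c[0] for c in role_map.combinations]
        assert [r.combo_arm for r in r1[::3]] == combos

    def test_unresolved_arm_named_in_error(self, paperlike_dataset):
        from algesia_combo.io_model import ArmRoleMap

        rm = ArmRoleMap("CCI+NS", "sham", [("Ami 3+Aq 25", "Ami 3", "Aq 999")])
        with pytest.raises(Exception, match="Aq 999"):
            interaction_table(paperlike_dataset, rm)

    def test_frame_round_trip(self, paperlike_dataset, role_map):
        frame = interaction_frame(interaction_table(paperlike_dataset, role_map))
        assert len(frame) == 18
        assert set(frame["classification"]).issubset(
            {"potentiated", "additive", "sub_additive"}
        )
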
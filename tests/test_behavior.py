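"""Behavioral stage: exclusions, circular mixture EM, bias curve, t-tests."""

import numpy as np
import pandas as pd
import pytest

import wmreselect as w
from wmreselect.behavior import participant_mean_errors
from wmreselect.circular import signed_orientation_diff


def _reported_table(seed=21, n_participants=2, n_trials=648, **report_kw):
    cfg = w.TaskConfig(n_participants=n_participants,
                       n_trials_per_participant=n_trials, seed=seed)
    return w.sample_reports(w.make_trial_table(cfg), seed=seed + 1, **report_kw)


class TestExclusions:
    def test_slow_probe_response_removed(self, small_table):
        t = w.sample_reports(small_table, seed=1)
        t.loc[t.index[0], "rt_probe_ms"] = 6000.0
        kept, report, flags = w.apply_exclusions(t)
        assert t.index[0] not in kept.index
        assert report["n_removed"].sum() >= 1

    def test_clean_table_passes_untouched(self, small_table):
        t = w.sample_reports(small_table, seed=2)
        t["rt_probe_ms"] = 900.0
        t["interrupter_rt_ms"] = np.where(
            t["block_type"] == "interruption", 400.0, np.nan)
        t["interrupter_correct"] = np.where(
            t["block_type"] == "interruption", True, np.nan)
        kept, report, flags = w.apply_exclusions(t)
        assert len(kept) == len(t)
        assert not flags["excluded"].any()

    def test_participant_with_many_bad_trials_flagged(self, small_table):
        t = w.sample_reports(small_table, seed=3)
        t["rt_probe_ms"] = 900.0
        t["interrupter_rt_ms"] = np.where(
            t["block_type"] == "interruption", 400.0, np.nan)
        t["interrupter_correct"] = np.where(
            t["block_type"] == "interruption", True, np.nan)
        # participant 0: 20% of trials violate the interrupter deadline
        rows = t[(t["participant"] == 0)
                 & (t["block_type"] == "interruption")].index[:10]
        assert len(rows) / (t["participant"] == 0).sum() >= 0.2
        t.loc[rows, "interrupter_rt_ms"] = 900.0
        kept, report, flags = w.apply_exclusions(t)
        assert flags.loc[0, "too_many_rejected"]
        assert not flags.loc[1:, "too_many_rejected"].any()
        assert (kept["participant"] == 1).sum() == (t["participant"] == 1).sum()

    def test_missing_columns_signalled(self):
        with pytest.raises(ValueError, match="missing required columns"):
            w.apply_exclusions(pd.DataFrame({"participant": [1]}))


class TestMixture:
    def test_pure_target_reports_fit_to_target_component(self):
        t = _reported_table(p_target=1.0, p_nontarget=0.0, p_guess=0.0,
                            kappa=w.kappa_from_sd_deg(5.0), n_participants=1)
        sub = t[t["block_type"] == "interruption"]
        fit = w.fit_mixture(
            signed_orientation_diff(sub["reported_orientation"], sub["target_orientation"]),
            signed_orientation_diff(sub["reported_orientation"], sub["interrupter_orientation"]))
        assert fit.p_target > 0.95 and fit.p_guess < 0.05

    def test_uniform_reports_fit_to_guessing(self):
        """Uniform reports load on the guess component. With finite n the
        memory components absorb some density fluctuations (their κ pins
        to the identifiability floor), so guessing dominates rather than
        reaching exactly 1."""
        t = _reported_table(p_target=0.0, p_nontarget=0.0, p_guess=1.0,
                            n_participants=1)
        sub = t[t["block_type"] == "interruption"]
        fit = w.fit_mixture(
            signed_orientation_diff(sub["reported_orientation"], sub["target_orientation"]),
            signed_orientation_diff(sub["reported_orientation"], sub["interrupter_orientation"]))
        assert fit.p_guess > 0.7
        assert fit.p_guess > max(fit.p_target, fit.p_nontarget)
        assert fit.kappa == pytest.approx(1.0)  # pinned at the floor

    def test_parameter_recovery_single_dataset(self):
        """Generator (0.95, 0.02, 0.03), 600+ trials, report SD 10°."""
        t = _reported_table(p_target=0.95, p_nontarget=0.02, p_guess=0.03,
                            kappa=w.kappa_from_sd_deg(10.0), n_participants=1,
                            n_trials=912, seed=42)
        sub = t[t["block_type"] == "interruption"]
        assert len(sub) == 600
        fit = w.fit_mixture(
            signed_orientation_diff(sub["reported_orientation"], sub["target_orientation"]),
            signed_orientation_diff(sub["reported_orientation"], sub["interrupter_orientation"]),
            seed=0)
        np.testing.assert_allclose(fit.proportions, [0.95, 0.02, 0.03], atol=0.03)
        assert fit.kappa == pytest.approx(w.kappa_from_sd_deg(10.0), rel=0.2)

    def test_proportions_sum_to_one_and_dominate_nested_model(self):
        t = _reported_table(p_target=0.8, p_nontarget=0.1, p_guess=0.1,
                            n_participants=1, seed=33)
        sub = t[t["block_type"] == "interruption"]
        et = signed_orientation_diff(sub["reported_orientation"], sub["target_orientation"])
        en = signed_orientation_diff(sub["reported_orientation"], sub["interrupter_orientation"])
        fit = w.fit_mixture(et, en)
        assert fit.proportions.sum() == pytest.approx(1.0, abs=1e-6)
        # target-only von Mises at its own ML optimum
        from scipy.special import i0e
        from wmreselect.circular import to_doubled_radians
        x = to_doubled_radians(et)
        rbar = np.hypot(np.cos(x).mean(), np.sin(x).mean())
        from wmreselect.behavior import _a1_inv
        k = _a1_inv(rbar)
        ll0 = np.sum(k * np.cos(x - np.arctan2(np.sin(x).sum(), np.cos(x).sum()))
                     - np.log(2 * np.pi * i0e(k)) - k)
        assert fit.log_likelihood >= ll0 - 1e-6

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            w.fit_mixture([1.0, 2.0], [1.0])


class TestBiasCurve:
    def test_null_generator_flat_curve(self):
        t = _reported_table(bias_gain=0.0, seed=55, n_participants=4)
        curve = w.response_bias_curve(t)
        assert np.abs(curve.mean).max() < 2.0

    def test_attractive_generator_sign_pattern(self):
        t = _reported_table(bias_gain=4.0, seed=56, n_participants=4)
        curve = w.response_bias_curve(t)
        pos = curve.mean[(curve.bin_centers >= 10) & (curve.bin_centers <= 45)]
        neg = curve.mean[(curve.bin_centers <= -10) & (curve.bin_centers >= -45)]
        assert pos.mean() > 0.5 and neg.mean() < -0.5

    def test_mirror_relabeling_reflects_curve_through_origin(self):
        t = _reported_table(bias_gain=3.0, seed=57)
        mirrored = t.copy()
        for col in ("target_orientation", "interrupter_orientation",
                    "reported_orientation"):
            mirrored[col] = -t[col]
        c, cm = w.response_bias_curve(t), w.response_bias_curve(mirrored)
        # bin at −x of the mirrored curve equals −(bin at +x), ±90 shared
        np.testing.assert_allclose(cm.bias[:, ::-1][:, 1:-1], -c.bias[:, 1:-1],
                                   atol=1e-9)

    def test_no_interrupter_trials_rejected(self, small_table):
        t = small_table[small_table["block_type"] == "no-interruption"]
        with pytest.raises(ValueError):
            w.response_bias_curve(t)


class TestGroupTests:
    def test_identical_conditions_give_zero_t_and_d(self):
        df = pd.DataFrame({"no-interruption": [10.0, 12, 11, 9],
                           "interruption": [10.0, 12, 11, 9]})
        out = w.chance_and_condition_tests(df)
        res = out["interruption_vs_no_interruption"]
        assert res.t == 0 and res.d == 0

    def test_hand_computed_paired_case(self):
        df = pd.DataFrame({"no-interruption": [10.0, 10, 10],
                           "interruption": [10.5, 11.0, 11.5]})
        res = w.chance_and_condition_tests(df)["interruption_vs_no_interruption"]
        # diffs (0.5, 1.0, 1.5): mean 1, sd 0.5 → t = √3·2, d = 2
        assert res.t == pytest.approx(1.0 / (0.5 / np.sqrt(3)))
        assert res.d == pytest.approx(2.0)

    def test_chance_comparison_uses_45_degrees(self):
        df = pd.DataFrame({"interruption": [45.0, 45, 45, 45]})
        res = w.chance_and_condition_tests(df)["interruption_vs_chance"]
        assert res.t == 0

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            w.chance_and_condition_tests(pd.DataFrame({"interruption": [10.0]}))

    def test_participant_means_pipeline(self):
        t = _reported_table(seed=60)
        means = participant_mean_errors(t)
        assert set(means.columns) == {"no-interruption", "interruption"}
        assert (means < 45).all().all()
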
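"""Generator contracts: balanced design, determinism, mixture reports,
gaze artifacts, and lateralized oscillatory epochs."""

import numpy as np
import pandas as pd
import pytest

import wmreselect as w
from wmreselect.circular import orientation_error
from wmreselect.synthetic_data import _trial_weights


class TestTrialTable:
    def test_full_design_block_counts(self):
        cfg = w.TaskConfig(n_participants=1, n_trials_per_participant=648, seed=0)
        t = w.make_trial_table(cfg)
        blocks = t.groupby("block_type")["block"].nunique()
        assert blocks["no-interruption"] == 9
        assert blocks["interruption"] == 18
        # fixed blocks split evenly over the three onsets
        fixed = t[t["predictability"] == "fixed"]
        assert fixed.groupby("onset_condition")["block"].nunique().tolist() == [3, 3, 3]

    def test_smallest_balanced_design_has_one_trial_per_cell(self):
        cfg = w.TaskConfig(n_participants=1, n_trials_per_participant=4, seed=1)
        t = w.make_trial_table(cfg)
        cells = t.groupby(["cued_side", "response_hand"]).size()
        assert len(cells) == 4 and (cells == 1).all()

    def test_tilt_sign_determines_response_hand(self, small_table):
        sign = np.sign(small_table["target_orientation"])
        hand = np.where(sign < 0, "left", "right")
        assert (hand == small_table["response_hand"]).all()

    def test_counterbalancing_side_hand_independent(self):
        cfg = w.TaskConfig(n_participants=1, n_trials_per_participant=648, seed=2)
        t = w.make_trial_table(cfg)
        side = (t["cued_side"] == "right").to_numpy(float)
        hand = (t["response_hand"] == "right").to_numpy(float)
        assert abs(np.corrcoef(side, hand)[0, 1]) < 0.1

    def test_seed_determinism(self, small_cfg, small_table):
        assert w.make_trial_table(small_cfg).equals(small_table)
        other = w.make_trial_table(
            w.TaskConfig(n_participants=4, n_trials_per_participant=48, seed=12))
        assert not other.equals(small_table)

    @pytest.mark.parametrize("kwargs", [
        {"n_trials_per_participant": 0},
        {"n_participants": -1},
        {"interrupter_onsets_ms": (1400, 600, 2400)},
        {"interrupter_onsets_ms": (600, 1400, 9000)},
        {"sampling_rate_hz": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            w.TaskConfig(**kwargs)


class TestReports:
    def test_noiseless_pure_target_limit(self, small_table):
        t = w.sample_reports(small_table, 1.0, 0.0, 0.0, kappa=np.inf,
                             bias_gain=0.0, seed=3)
        np.testing.assert_allclose(
            orientation_error(t["reported_orientation"], t["target_orientation"]),
            0.0, atol=1e-9)

    def test_pure_guessing_hits_45_degree_chance(self):
        cfg = w.TaskConfig(n_participants=3, n_trials_per_participant=648, seed=4)
        t = w.sample_reports(w.make_trial_table(cfg), 0.0, 0.0, 1.0, seed=5)
        err = orientation_error(t["reported_orientation"], t["target_orientation"])
        assert err.mean() == pytest.approx(45.0, abs=2.0)

    def test_bad_proportions_rejected(self, small_table):
        with pytest.raises(ValueError):
            w.sample_reports(small_table, 0.9, 0.2, 0.1)
        with pytest.raises(ValueError):
            w.sample_reports(small_table, 1.1, -0.2, 0.1)

    def test_attractive_bias_shifts_reports_toward_interrupter(self):
        cfg = w.TaskConfig(n_participants=2, n_trials_per_participant=648, seed=6)
        t = w.sample_reports(w.make_trial_table(cfg), 1.0, 0.0, 0.0,
                             kappa=np.inf, bias_gain=5.0, seed=7)
        sub = t[t["block_type"] == "interruption"]
        from wmreselect.circular import signed_orientation_diff
        err = signed_orientation_diff(sub["reported_orientation"],
                                      sub["target_orientation"])
        diff = signed_orientation_diff(sub["interrupter_orientation"],
                                       sub["target_orientation"])
        # sign of the report shift follows the sign of the difference
        assert (np.sign(err[np.abs(diff) > 5]) ==
                np.sign(diff[np.abs(diff) > 5])).mean() > 0.95


class TestGaze:
    def test_blinks_produce_saturated_segments(self, small_table, small_cfg):
        sub = small_table[small_table["participant"] == 0]
        raw = w.sample_gaze(sub, small_cfg, blink_rate=0.5, seed=8)
        n_blinks = sum(len(b) for b in raw.blink_intervals)
        assert n_blinks > 0
        i = next(i for i, b in enumerate(raw.blink_intervals) if b)
        b0, b1 = raw.blink_intervals[i][0]
        inside = (raw.times_ms >= b0) & (raw.times_ms <= b1)
        assert (raw.x_left[i, inside] == -30.0).all()

    def test_zero_amplitude_yields_null_towardness(self, small_cfg):
        cfg = w.TaskConfig(n_participants=1, n_trials_per_participant=200,
                           seed=9, block_size=4)
        t = w.make_trial_table(cfg)
        raw = w.sample_gaze(t, cfg, towardness_amp=0.0, blink_rate=0.0, seed=10)
        ep = w.preprocess_gaze(raw)
        surv = t.loc[ep.table_index]
        tw = w.towardness(ep.x[(surv["cued_side"] == "right").to_numpy()],
                          ep.x[(surv["cued_side"] == "left").to_numpy()])
        assert np.abs(tw).max() < 0.15  # noise floor only

    def test_amplitude_recovered_in_towardness(self):
        cfg = w.TaskConfig(n_participants=1, n_trials_per_participant=200,
                           seed=9, block_size=4)
        t = w.make_trial_table(cfg)
        raw = w.sample_gaze(t, cfg, towardness_amp=0.4, blink_rate=0.0, seed=10)
        ep = w.preprocess_gaze(raw)
        surv = t.loc[ep.table_index]
        tw = w.towardness(ep.x[(surv["cued_side"] == "right").to_numpy()],
                          ep.x[(surv["cued_side"] == "left").to_numpy()])
        peak = tw[(ep.times_ms > 200) & (ep.times_ms < 900)].max()
        assert peak == pytest.approx(0.4, abs=0.15)

    def test_excessive_amplitude_rejected(self, small_table, small_cfg):
        with pytest.raises(ValueError):
            w.sample_gaze(small_table, small_cfg, towardness_amp=3.0)


class TestEpochs:
    def test_unknown_effect_channel_rejected(self, small_table, small_cfg):
        eff = w.NeuralEffectSpec(channel_pair=("PO3", "PO4"))
        with pytest.raises(ValueError):
            w.sample_epochs(small_table, small_cfg, effects=[eff])

    def test_attenuation_validation(self):
        with pytest.raises(ValueError):
            w.NeuralEffectSpec(contra_attenuation=1.0)

    def test_null_attenuation_gives_null_lateralization(self):
        cfg = w.TaskConfig(n_participants=3, n_trials_per_participant=144, seed=13)
        t = w.make_trial_table(cfg)
        eps = w.sample_epochs(t, cfg, effects=w.default_neural_effects(0.0, 0.0),
                              seed=13)
        lat = w.cohort_lateralization(eps, t, freqs=np.arange(8, 13, 2.0), decim=4)
        course = w.band_course(lat, (8, 12))
        assert np.abs(course.course.mean(axis=0)).max() < 8.0

    def test_alpha_attenuation_appears_in_cue_window(self):
        cfg = w.TaskConfig(n_participants=2, n_trials_per_participant=144, seed=14)
        t = w.make_trial_table(cfg)
        eps = w.sample_epochs(t, cfg, seed=14)
        lat = w.cohort_lateralization(eps, t, freqs=np.arange(8, 13, 2.0), decim=4)
        m = w.band_course(lat, (8, 12)).course.mean(axis=0)
        times = lat.times_ms
        inside = m[(times > 300) & (times < 600)].mean()
        outside = m[(times > 1500) & (times < 2000)].mean()
        assert inside < -8 and abs(outside) < 6

    def test_seed_determinism(self, small_table, small_cfg):
        a = w.sample_epochs(small_table, small_cfg, seed=15)
        b = w.sample_epochs(small_table, small_cfg, seed=15)
        np.testing.assert_array_equal(a.data, b.data)

    def test_hdf5_round_trip(self, small_table, small_cfg, tmp_path):
        a = w.sample_epochs(small_table, small_cfg, seed=16)
        a.save(tmp_path / "epochs.h5")
        b = w.EpochArray.load(tmp_path / "epochs.h5")
        np.testing.assert_array_equal(a.data, b.data)
        assert b.channels == a.channels and b.sfreq == a.sfreq
        np.testing.assert_array_equal(a.times_ms, b.times_ms)

    def test_motor_delay_shifts_response_locked_window(self, small_cfg):
        t = pd.DataFrame({"onset_ms": [600.0], "interrupter_rt_ms": [400.0]})
        times = small_cfg.times_ms()
        for delay in (0.0, 200.0):
            eff = w.NeuralEffectSpec(
                windows=(w.EffectWindow(0.0, 400.0, "transient", "response"),),
                motor_delay_ms=delay)
            wgt = _trial_weights(times, eff, t["onset_ms"].to_numpy(),
                                 (t["onset_ms"] + t["interrupter_rt_ms"]).to_numpy(),
                                 small_cfg)
            first = times[np.flatnonzero(wgt[0] > 0)[0]]
            assert first == pytest.approx(1000.0 + delay, abs=8)
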
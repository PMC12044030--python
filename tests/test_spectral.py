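"""Time–frequency decomposition, lateralization indices, re-epoching."""

import numpy as np
import pytest

import wmreselect as w
from wmreselect.spectral import TFR, epoch_around_event, lateralization_index


def _tone(freq, sfreq=250.0, dur_s=2.0, amp=1.0):
    t = np.arange(0, dur_s, 1 / sfreq)
    return amp * np.sin(2 * np.pi * freq * t)[None, None, :], t * 1000.0


class TestMorletTFR:
    def test_pure_tone_ridge_at_input_frequency(self):
        sig, _ = _tone(10.0)
        tfr = w.morlet_tfr(sig, 250.0, freqs=np.arange(4, 21, 1.0),
                           channels=["A"])
        prof = tfr.power[0, 0][:, tfr.edge_valid].mean(axis=1)
        assert tfr.freqs[prof.argmax()] == 10.0
        # stationary tone → power flat in time away from edges
        ridge = tfr.power[0, 0, prof.argmax(), tfr.edge_valid]
        assert ridge.std() / ridge.mean() < 0.05

    def test_zero_signal_zero_power(self):
        tfr = w.morlet_tfr(np.zeros((1, 1, 500)), 250.0,
                           freqs=np.array([8.0, 12.0]))
        np.testing.assert_allclose(tfr.power, 0.0, atol=1e-20)

    def test_power_scales_with_input_variance(self):
        """Doubling amplitude quadruples wavelet power (linearity check)."""
        s1, _ = _tone(12.0, amp=1.0)
        s2, _ = _tone(12.0, amp=2.0)
        f = np.array([12.0])
        p1 = w.morlet_tfr(s1, 250.0, freqs=f)
        p2 = w.morlet_tfr(s2, 250.0, freqs=f)
        ratio = p2.power[0, 0, 0, p2.edge_valid] / p1.power[0, 0, 0, p1.edge_valid]
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-6)

    def test_white_noise_power_tracks_variance_linearly(self, rng):
        """Total wavelet power of white noise grows ∝ input variance."""
        n = rng.standard_normal((4, 1, 4000))
        f = np.arange(5, 31, 5.0)
        lo = w.morlet_tfr(1.0 * n, 250.0, freqs=f)
        hi = w.morlet_tfr(3.0 * n, 250.0, freqs=f)
        slope = hi.power.sum() / lo.power.sum()
        assert slope == pytest.approx(9.0, rel=0.05)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            w.morlet_tfr(np.zeros((1, 1, 500)), 100.0, freqs=np.array([60.0]))

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            w.morlet_tfr(np.zeros((1, 1, 50)), 250.0, freqs=np.array([10.0]))

    def test_edge_samples_flagged(self):
        sig, tms = _tone(10.0)
        tfr = w.morlet_tfr(sig, 250.0, freqs=np.array([10.0]), times_ms=tms)
        assert not tfr.edge_valid[0] and not tfr.edge_valid[-1]
        assert tfr.edge_valid[(tfr.times_ms > 200) & (tfr.times_ms < 1800)].all()


def _pair_tfr(contra_power, ipsi_power):
    """4-trial TFR: trials 0,1 cued left; 2,3 cued right; channels PO7, PO8."""
    p = np.empty((4, 2, 1, 3))
    # PO7 (left hemi): contra on right-cued trials (2,3)
    p[2:, 0], p[:2, 0] = contra_power, ipsi_power
    # PO8 (right hemi): contra on left-cued trials (0,1)
    p[:2, 1], p[2:, 1] = contra_power, ipsi_power
    feat = np.array(["left", "left", "right", "right"])
    tfr = TFR(power=p, freqs=np.array([10.0]),
              times_ms=np.array([0.0, 4.0, 8.0]),
              channels=["PO7", "PO8"], sfreq=250.0)
    return tfr, feat


class TestLateralization:
    def test_equal_power_gives_zero(self):
        tfr, feat = _pair_tfr(2.0, 2.0)
        np.testing.assert_allclose(lateralization_index(tfr, feat), 0.0)

    def test_contra_one_ipsi_three_gives_minus_fifty(self):
        tfr, feat = _pair_tfr(1.0, 3.0)
        np.testing.assert_allclose(lateralization_index(tfr, feat), -50.0)

    def test_antisymmetric_under_condition_swap(self):
        tfr, feat = _pair_tfr(1.0, 3.0)
        swapped = np.where(feat == "left", "right", "left")
        np.testing.assert_allclose(lateralization_index(tfr, feat),
                                   -lateralization_index(tfr, swapped))

    def test_bounded_by_hundred(self, rng):
        p = rng.uniform(0, 5, size=(10, 2, 3, 7))
        tfr = TFR(power=p, freqs=np.arange(3.0, 6.0),
                  times_ms=np.arange(7.0) * 4, channels=["PO7", "PO8"],
                  sfreq=250.0)
        feat = np.array(["left", "right"] * 5)
        idx = lateralization_index(tfr, feat)
        assert np.nanmax(np.abs(idx)) <= 100.0

    def test_zero_denominator_propagates_nan(self):
        tfr, feat = _pair_tfr(0.0, 0.0)
        assert np.isnan(lateralization_index(tfr, feat)).all()

    def test_missing_channel_rejected(self):
        tfr, feat = _pair_tfr(1.0, 2.0)
        with pytest.raises(KeyError):
            lateralization_index(tfr, feat, pair=("C3", "C4"))

    def test_single_condition_rejected(self):
        tfr, _ = _pair_tfr(1.0, 2.0)
        with pytest.raises(ValueError):
            lateralization_index(tfr, np.array(["left"] * 4))


class TestBandCourse:
    def _lat(self, values):
        return w.TFRLateralization(
            index=values, freqs=np.array([8.0, 10.0, 12.0]),
            times_ms=np.arange(4.0) * 4, channel_pair=("PO7", "PO8"),
            basis="item-side", edge_valid=np.ones(4, bool))

    def test_constant_index_passes_through(self):
        lat = self._lat(np.full((2, 3, 4), -7.0))
        np.testing.assert_allclose(w.band_course(lat, (8, 12)).course, -7.0)

    def test_single_frequency_band_equals_row(self):
        vals = np.arange(24.0).reshape(2, 3, 4)
        lat = self._lat(vals)
        np.testing.assert_allclose(w.band_course(lat, (10, 10)).course,
                                   vals[:, 1, :])

    def test_band_outside_axis_rejected(self):
        with pytest.raises(ValueError):
            w.band_course(self._lat(np.zeros((2, 3, 4))), (30, 40))


class TestTopography:
    def test_identical_conditions_zero_map_and_antisymmetry(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1, 2, (6, 3, 2, 5))
        tfr = TFR(power=p, freqs=np.array([8.0, 12.0]),
                  times_ms=np.arange(5.0) * 4,
                  channels=["PO7", "PO8", "POz"], sfreq=250.0)
        same = np.array(["left"] * 3 + ["right"] * 3)
        m = w.topography_contrast(tfr, same, (8, 12), [(0, 20)])
        # swapping labels flips the sign
        swapped = np.where(same == "left", "right", "left")
        m2 = w.topography_contrast(tfr, swapped, (8, 12), [(0, 20)])
        np.testing.assert_allclose(m.to_numpy(), -m2.to_numpy(), atol=1e-12)
        # identical trials in both conditions → zero map
        p2 = np.tile(p[:1], (6, 1, 1, 1))
        tfr2 = TFR(power=p2, freqs=tfr.freqs, times_ms=tfr.times_ms,
                   channels=tfr.channels, sfreq=250.0)
        z = w.topography_contrast(tfr2, same, (8, 12), [(0, 20)])
        np.testing.assert_allclose(z.to_numpy(), 0.0, atol=1e-12)


class TestEpochAroundEvent:
    times = np.arange(-200.0, 1001.0, 4.0)

    def test_sample_exact_alignment_against_direct_indexing(self, rng):
        data = rng.standard_normal((5, 2, self.times.size))
        events = np.array([0.0, 100.0, 250.0, 400.0, 500.0])
        new, ntimes, kept = epoch_around_event(data, self.times, events,
                                               250.0, (-100, 100))
        assert kept.all()
        assert ntimes[0] == -100 and ntimes[-1] == 100
        for i, ev in enumerate(events):
            c = int(round((ev - self.times[0]) / 4.0))
            np.testing.assert_array_equal(new[i], data[i, :, c - 25:c + 26])

    def test_event_at_zero_is_identity_on_central_window(self, rng):
        data = rng.standard_normal((1, 1, self.times.size))
        new, ntimes, kept = epoch_around_event(data, self.times,
                                               np.array([0.0]), 250.0,
                                               (-200, 200))
        sel = (self.times >= -200) & (self.times <= 200)
        np.testing.assert_array_equal(new[0, 0], data[0, 0, sel])

    def test_event_near_edge_dropped_and_reported(self, rng):
        data = rng.standard_normal((3, 1, self.times.size))
        events = np.array([500.0, 950.0, np.nan])
        new, _, kept = epoch_around_event(data, self.times, events, 250.0,
                                          (-100, 100))
        assert list(kept) == [True, False, False]
        assert new.shape[0] == 1
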
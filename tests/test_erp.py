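"""Epoch segmentation, baseline correction, artifact rejection, FRN peak
localization, and windowed single-trial amplitude scoring."""

import numpy as np
import pandas as pd
import pytest

from rlerp.erp import (
    EpochSet,
    frn_peak_latency,
    p3_amplitude,
    reject_artifacts,
    segment_and_baseline,
    single_trial_frn,
)

SFREQ = 1000.0
CHANNELS = ["FCz", "Pz"]
ROLES = {"frn_p3a": "FCz", "p3b": "Pz"}


def keys(n):
    return pd.DataFrame(
        {
            "participant": ["p1"] * n,
            "session": ["immediate"] * n,
            "trial_index": range(n),
            "feedback_valence": ["positive"] * n,
            "learnability": ["learnable"] * n,
        }
    )


def epochs_from(data):
    data = np.asarray(data, dtype=float)
    return EpochSet(
        data=data,
        sfreq=SFREQ,
        tmin_s=-0.2,
        channel_names=CHANNELS,
        channel_roles=ROLES,
        trial_keys=keys(data.shape[0]),
    )


class TestSegmentation:
    def test_epoch_length_and_constant_signal_zeroed(self):
        continuous = np.full((2, 5000), 7.3)
        epochs, dropped = segment_and_baseline(
            continuous, np.array([1000.0, 2500.0]), SFREQ, CHANNELS, ROLES, keys(2)
        )
        assert epochs.data.shape == (2, 2, 800)  # 800 ms at 1000 Hz
        assert dropped == []
        np.testing.assert_allclose(epochs.data, 0.0, atol=1e-12)

    def test_ramp_baseline_subtraction_closed_form(self):
        # x(t) = t (samples); baseline over samples [800, 1000) has mean 899.5
        continuous = np.tile(np.arange(5000.0), (2, 1))
        epochs, _ = segment_and_baseline(
            continuous, np.array([1000.0]), SFREQ, CHANNELS, ROLES, keys(1)
        )
        expected = np.arange(800.0, 1600.0) - 899.5
        np.testing.assert_allclose(epochs.data[0, 0], expected)

    def test_onset_too_close_to_edge_dropped(self):
        continuous = np.zeros((2, 1200))
        epochs, dropped = segment_and_baseline(
            continuous, np.array([100.0, 400.0]), SFREQ, CHANNELS, ROLES, keys(2)
        )
        assert dropped == [0]
        assert epochs.data.shape[0] == 1

    def test_scoring_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 3, (2, 4000))
        e1, _ = segment_and_baseline(base, np.array([1000.0]), SFREQ, CHANNELS, ROLES, keys(1))
        e2, _ = segment_and_baseline(base + 55.0, np.array([1000.0]), SFREQ, CHANNELS, ROLES, keys(1))
        np.testing.assert_allclose(e1.data, e2.data, atol=1e-9)


class TestArtifactRejection:
    def _quiet_epoch(self):
        t = np.arange(800)
        wave = 5.0 * np.sin(2 * np.pi * 10 * t / SFREQ)
        return np.stack([wave, wave])

    def test_smooth_sinusoid_retained(self):
        mask = reject_artifacts(epochs_from([self._quiet_epoch()]))
        assert not mask[0]

    def test_large_absolute_value_rejected(self):
        bad = self._quiet_epoch()
        bad[0, 400] = 150.0
        mask = reject_artifacts(epochs_from([self._quiet_epoch(), bad]))
        assert list(mask) == [False, True]

    def test_flat_epoch_rejected(self):
        flat = np.full((2, 800), 0.0)
        flat[:, ::2] = 0.05  # total range 0.05 uV < 0.1 uV
        mask = reject_artifacts(epochs_from([flat]))
        assert mask[0]

    def test_voltage_step_rejected(self):
        bad = self._quiet_epoch()
        bad[1, 300:] += 60.0  # 60 uV jump in one 1-ms sample
        mask = reject_artifacts(epochs_from([bad]))
        assert mask[0]

    def test_peak_to_peak_range_rejected(self):
        t = np.arange(800)
        slow = 51.0 * np.sin(2 * np.pi * 1.0 * t / SFREQ)  # range 102 uV, steps small
        mask = reject_artifacts(epochs_from([np.stack([slow, slow])]))
        assert mask[0]

    def test_rejection_rate_matches_planted_violations(self):
        rng = np.random.default_rng(4)
        epochs = []
        planted = []
        for _ in range(200):
            e = self._quiet_epoch() + rng.normal(0, 1, (2, 800))
            bad = rng.random() < 0.25
            if bad:
                e[0, rng.integers(0, 800)] = 140.0
            planted.append(bad)
            epochs.append(e)
        mask = reject_artifacts(epochs_from(epochs))
        assert list(mask) == planted


class TestFrnPeak:
    times = np.arange(800) - 200.0

    def test_gaussian_trough_localized(self):
        wave = -3.0 * np.exp(-((self.times - 260.0) ** 2) / (2 * 15.0**2))
        assert frn_peak_latency(wave, self.times) == pytest.approx(260.0)

    def test_monotone_segment_has_no_peak(self):
        wave = -0.01 * self.times  # strictly decreasing: no local minimum
        assert frn_peak_latency(wave, self.times) is None

    def test_equal_troughs_take_earliest(self):
        wave = np.zeros_like(self.times)
        for c in (240.0, 300.0):
            wave -= 2.0 * np.exp(-((self.times - c) ** 2) / (2 * 5.0**2))
        assert frn_peak_latency(wave, self.times) == pytest.approx(240.0)

    def test_window_endpoints_excluded(self):
        wave = np.zeros_like(self.times)
        wave[self.times == 200.0] = -5.0  # trough exactly on the boundary
        assert frn_peak_latency(wave, self.times) is None


class TestAmplitudes:
    times = np.arange(800) - 200.0

    def test_constant_epoch_scores_its_value(self):
        const = np.full(800, 4.2)
        assert single_trial_frn(const, self.times, 250.0) == pytest.approx(4.2)
        assert p3_amplitude(const, self.times) == pytest.approx(4.2)

    def test_frn_window_spans_40_ms(self):
        sel = (self.times >= 230.0) & (self.times <= 270.0)
        indicator = np.where(sel, 1.0, 0.0)
        assert single_trial_frn(indicator, self.times, 250.0) == pytest.approx(1.0)
        assert sel.sum() == 41  # 40 ms inclusive at 1000 Hz

    def test_ramp_scores_value_at_peak_latency(self):
        ramp = 0.05 * self.times
        assert single_trial_frn(ramp, self.times, 250.0) == pytest.approx(0.05 * 250.0)

    def test_missing_latency_gives_nan(self):
        assert np.isnan(single_trial_frn(np.zeros(800), self.times, None))

    def test_p3_indicator_mean(self):
        sel = (self.times >= 300.0) & (self.times <= 500.0)
        indicator = np.where(sel, 1.0, 0.0)
        assert p3_amplitude(indicator, self.times) == pytest.approx(1.0)

    def test_p3_toy_window_hand_mean(self):
        # five-sample toy at 10 Hz sampling: window covers samples at
        # 300 and 400 ms -> mean of (2, 6)
        times = np.array([100.0, 200.0, 300.0, 400.0, 600.0])
        epoch = np.array([9.0, 9.0, 2.0, 6.0, 9.0])
        assert p3_amplitude(epoch, times) == pytest.approx(4.0)

    def test_frn_p3a_windows_share_300_350(self):
        # both quantities are computable from one epoch despite the overlap
        wave = np.where((self.times >= 300) & (self.times <= 350), 1.0, 0.0)
        frn = single_trial_frn(wave, self.times, 330.0)
        p3a = p3_amplitude(wave, self.times)
        assert frn > 0 and p3a > 0


class TestPreprocessing:
    def test_bandpass_removes_out_of_band_component(self):
        from rlerp.erp import preprocess_continuous

        t = np.arange(40_000) / SFREQ  # long enough for the 0.1 Hz high-pass
        in_band = 4.0 * np.sin(2 * np.pi * 10 * t)
        out_of_band = 4.0 * np.sin(2 * np.pi * 45 * t)
        x = np.stack([in_band + out_of_band, in_band + out_of_band])
        filtered = preprocess_continuous(x, SFREQ, notch_hz=None)
        mid = slice(10_000, 30_000)  # avoid filter edge effects
        assert np.std(filtered[0, mid] - in_band[mid]) < 0.3 * np.std(out_of_band)
        assert np.corrcoef(filtered[0, mid], in_band[mid])[0, 1] > 0.98


class TestEpochIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        eps = epochs_from(rng.normal(0, 5, (3, 2, 800)))
        reject_artifacts(eps)
        eps.save(tmp_path / "epochs.npy", tmp_path / "epochs.json")
        back = EpochSet.load(tmp_path / "epochs.npy", tmp_path / "epochs.json")
        np.testing.assert_allclose(back.data, eps.data)
        assert back.channel_roles == eps.channel_roles
        np.testing.assert_array_equal(back.rejection_mask, eps.rejection_mask)
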
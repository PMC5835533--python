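"""Filtering, artifact rejection, condition collapsing and averaging."""

import numpy as np
import pytest
from scipy import signal

import mttpipe as m
from mttpipe.preprocess import RejectionError

from conftest import small_config


def _sine_epochs(freq_hz, fs=1024.0, n_trials=4, amp=5.0):
    dt = 1000.0 / fs
    times = -100.0 + dt * np.arange(int(900 / dt) + 2)
    wave = amp * np.sin(2 * np.pi * freq_hz * times / 1000.0)
    data = np.tile(wave, (n_trials, 1, 1))
    return m.EpochSet(
        data=data,
        times=times,
        fs=fs,
        condition=np.array(["now", "now", "then", "then"], dtype=object),
        rejected=np.zeros(n_trials, dtype=bool),
        electrode_ids=["e0"],
    )


class TestBandpass:
    def test_dc_is_removed(self):
        ep = _sine_epochs(10.0)
        ep.data[:] = 5.0
        out = m.bandpass(ep)
        interior = slice(60, -60)
        assert np.max(np.abs(out.data[:, :, interior])) < 1e-6 * 5.0

    @pytest.mark.parametrize(
        "freq,check",
        [(50.0, lambda g: g > 0.95), (200.0, lambda g: g < 0.10)],
    )
    def test_frequency_response_from_filtered_impulse(self, freq, check):
        """Gain measured two ways: FFT of the filtered impulse (oracle) and
        mid-epoch amplitude of a filtered sinusoid; both must agree with the
        passband/stopband expectation at fs = 1024 Hz."""
        fs = 1024.0
        ep = _sine_epochs(freq, fs=fs)
        n = ep.n_samples
        imp = ep.copy()
        imp.data = np.zeros_like(imp.data)
        imp.data[:, :, n // 2] = 1.0
        h = m.bandpass(imp).data[0, 0]
        gains = np.abs(np.fft.rfft(h))
        f_axis = np.fft.rfftfreq(n, d=1.0 / fs)
        gain_fft = gains[np.argmin(np.abs(f_axis - freq))]
        assert check(gain_fft)
        # sinusoid amplitude recovered by quadrature projection mid-epoch,
        # so the filter's low-frequency edge transient does not contaminate
        # the stopband measurement
        out = m.bandpass(ep)
        mid = slice(n // 2 - 100, n // 2 + 100)
        t_mid = ep.times[mid] / 1000.0
        phasor = np.exp(2j * np.pi * freq * t_mid)
        gain_sine = 2.0 * np.abs(out.data[0, 0, mid] @ phasor.conj()) / len(t_mid) / 5.0
        assert check(gain_sine)
        assert gain_sine == pytest.approx(gain_fft, abs=0.05)

    def test_corner_above_nyquist_rejected(self):
        ep, _ = m.generate_dataset(small_config())
        with pytest.raises(ValueError, match="Nyquist"):
            m.bandpass(ep, 1.0, 300.0)
        with pytest.raises(ValueError):
            m.bandpass(ep, 120.0, 1.0)


class TestRejectEpochs:
    def test_planted_transient_is_flagged(self):
        cfg = small_config(noise_sd=2.0)
        epochs, _ = m.generate_dataset(cfg)
        target = 11
        times = epochs.times
        burst = 10 * 2.0 * np.exp(-((times - 350.0) ** 2) / (2 * 15.0**2))
        epochs.data[target] += burst[None, :]
        out = m.reject_epochs(m.bandpass(epochs))
        assert out.rejected[target]

    def test_infinite_threshold_rejects_nothing(self):
        epochs, _ = m.generate_dataset(small_config(artifact_rate=0.2))
        out = m.reject_epochs(epochs, z_threshold=np.inf)
        assert out.rejected.sum() == 0

    def test_false_positive_rate_is_low_on_clean_data(self):
        """Artifact-free data: <= 5% of trials flagged in expectation."""
        total, flagged = 0, 0
        for seed in range(25):
            epochs, _ = m.generate_dataset(small_config(seed=seed))
            out = m.reject_epochs(m.bandpass(epochs))
            total += out.n_trials
            flagged += int(out.rejected.sum())
        assert flagged / total <= 0.05

    def test_existing_flags_are_kept(self):
        epochs, _ = m.generate_dataset(small_config())
        epochs.rejected[0] = True
        out = m.reject_epochs(epochs)
        assert out.rejected[0]

    def test_error_when_too_few_trials_would_remain(self):
        cfg = small_config(trials_per_condition=3, noise_sd=1.0)
        epochs, _ = m.generate_dataset(cfg)
        burst = 50.0 * np.exp(-((epochs.times - 300.0) ** 2) / (2 * 15.0**2))
        epochs.data[[0, 1, 3, 4]] += burst[None, :]
        with pytest.raises(RejectionError):
            m.reject_epochs(epochs)


class TestCollapseConditions:
    def _three_condition_epochs(self):
        rng = np.random.default_rng(0)
        n = 120
        cond = np.array(["past"] * 40 + ["future"] * 40 + ["now"] * 40, dtype=object)
        return m.EpochSet(
            data=rng.normal(size=(n, 2, 50)),
            times=np.arange(50) * (1000.0 / 512) - 19.53125,
            fs=512.0,
            condition=cond,
            rejected=np.zeros(n, dtype=bool),
            electrode_ids=["a", "b"],
        )

    def test_past_and_future_collapse_into_then(self):
        ep = self._three_condition_epochs()
        out = m.collapse_conditions(ep, {"past": "then", "future": "then", "now": "now"})
        assert int((out.condition == "then").sum()) == 80
        assert int((out.condition == "now").sum()) == 40
        assert out.n_trials == ep.n_trials
        np.testing.assert_array_equal(out.data, ep.data)

    def test_identity_mapping_changes_nothing(self):
        ep = self._three_condition_epochs()
        out = m.collapse_conditions(ep, {c: c for c in ep.conditions})
        assert list(out.condition) == list(ep.condition)

    def test_missing_label_is_an_error(self):
        ep = self._three_condition_epochs()
        with pytest.raises(ValueError, match="future"):
            m.collapse_conditions(ep, {"past": "then", "now": "now"})


class TestAverageEvoked:
    def test_noise_free_evoked_equals_injected_template(self, noisefree_dataset):
        from mttpipe.synthetic import condition_templates

        epochs, meta = noisefree_dataset
        cfg = m.GeneratorConfig(seed=0, noise_sd=0.0, artifact_rate=0.0, polarity_flip_prob=0.0)
        ev = m.average_evoked(epochs)
        tpl = condition_templates(cfg, "LTC")
        np.testing.assert_allclose(ev.waveform("l_ltc01", "now"), tpl["now"], atol=1e-12)
        np.testing.assert_allclose(ev.waveform("l_ltc01", "then"), tpl["then"], atol=1e-12)

    def test_two_constant_trials_average_to_their_mean(self):
        times = np.arange(50) * (1000.0 / 512) - 19.53125
        data = np.zeros((4, 1, 50))
        data[0] = 1.0
        data[1] = 3.0
        data[2] = data[3] = 7.0
        ep = m.EpochSet(
            data=data,
            times=times,
            fs=512.0,
            condition=np.array(["now", "now", "then", "then"], dtype=object),
            rejected=np.zeros(4, dtype=bool),
            electrode_ids=["e"],
        )
        ev = m.average_evoked(ep)
        assert np.all(ev.waveform("e", "now") == 2.0)

    def test_flagged_trials_are_excluded(self):
        rng = np.random.default_rng(3)
        times = np.arange(50) * (1000.0 / 512) - 19.53125
        data = rng.normal(size=(10, 2, 50))
        cond = np.array(["now"] * 5 + ["then"] * 5, dtype=object)
        rejected = np.zeros(10, dtype=bool)
        rejected[[1, 7]] = True
        ep = m.EpochSet(
            data=data, times=times, fs=512.0, condition=cond,
            rejected=rejected, electrode_ids=["a", "b"],
        )
        ev = m.average_evoked(ep)
        keep_now = [0, 2, 3, 4]
        np.testing.assert_allclose(ev.data[:, 0, :], data[keep_now].mean(axis=0), atol=1e-14)
        assert ev.n_trials[0, 0] == 4 and ev.n_trials[0, 1] == 4

    def test_trial_bookkeeping_is_conserved(self):
        epochs, _ = m.generate_dataset(small_config(artifact_rate=0.1, seed=3))
        out = m.reject_epochs(m.bandpass(epochs))
        ev = m.average_evoked(out)
        assert int(ev.n_trials[0].sum()) + int(out.rejected.sum()) == out.n_trials
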
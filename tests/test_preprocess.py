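"""Preprocessing contracts: Beer-Lambert conversion, filtering, segmentation
and time-frequency imaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chtlm.containers import ExtinctionMatrix, HemoRecording, OpticalRecording, default_extinction
from chtlm.preprocess import (
    bandpass,
    beer_lambert,
    cwt_image,
    measure_bandpass_gain,
    morlet_cwt,
    paradigm_events,
    segment_trials,
    select_channels,
    stft_image,
)


# ---------------------------------------------------------------- Beer-Lambert
class TestBeerLambert:
    def test_constant_intensity_gives_zero_concentration(self):
        inten = np.full((4, 2, 50), 3.7)
        opt = OpticalRecording(intensity=inten, fs=11.0)
        hemo = beer_lambert(opt)
        assert np.allclose(hemo.hbo, 0.0) and np.allclose(hemo.hbr, 0.0)

    def test_unit_construction(self):
        # eps = I, (d/10)*dpf = 1, I = I0/10 at both wavelengths -> dA = 1, dC = 1
        eps = ExtinctionMatrix(np.eye(2))
        inten = np.full((1, 2, 20), 0.1)
        opt = OpticalRecording(intensity=inten, fs=10.0, d_mm=10.0, dpf=(1.0, 1.0))
        hemo = beer_lambert(opt, eps=eps, i0=1.0)
        assert np.allclose(hemo.hbo, 1.0) and np.allclose(hemo.hbr, 1.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            OpticalRecording(intensity=np.zeros((1, 2, 5)), fs=10.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_random_recordings(self, seed):
        """beer_lambert inverts the synthetic raw-intensity construction to 1e-8."""
        from chtlm.synthetic import SynthConfig, generate_fnirs_subject, hemo_to_raw_intensity, raw_trial_to_optical

        cfg = SynthConfig(seed=seed, trials_per_class=1, n_channels_fnirs=4, task_s=5.0)
        ts = generate_fnirs_subject(cfg, "S1")
        raw = hemo_to_raw_intensity(ts)
        opt = raw_trial_to_optical(raw, 0)
        hemo = beer_lambert(opt, i0=1.0)
        rec = np.concatenate([hemo.hbo, hemo.hbr], axis=0)
        assert np.abs(rec - ts.data[0]).max() < 1e-8


# ------------------------------------------------------------ channel handling
class TestSelectChannels:
    def _rec(self):
        return HemoRecording(hbo=np.arange(40.0).reshape(4, 10), hbr=np.zeros((4, 10)),
                             fs=11.0, channel_names=["C1", "C2", "C3", "C4"])

    def test_keep_all_identity(self):
        rec = self._rec()
        out = select_channels(rec, rec.channel_names)
        assert np.array_equal(out.hbo, rec.hbo)

    def test_subset_and_reorder(self):
        out = select_channels(self._rec(), ["C3", "C1"])
        assert out.channel_names == ["C3", "C1"]
        assert np.array_equal(out.hbo[1], np.arange(10.0))

    def test_unknown_name_reported(self):
        with pytest.raises(ValueError, match="Cz99"):
            select_channels(self._rec(), ["C1", "Cz99"])


# ------------------------------------------------------------------- filtering
class TestBandpass:
    @pytest.mark.parametrize("freq,kind", [(0.005, "stop"), (0.05, "pass"), (0.1, "pass"),
                                           (0.3, "transition"), (1.0, "stop")])
    def test_frequency_response(self, freq, kind):
        g = measure_bandpass_gain(freq)
        if kind == "pass":
            assert g >= 0.9
        elif kind == "stop":
            assert g <= 0.1
        else:
            assert g <= 0.5

    def test_dc_rejected(self):
        x = np.ones((1, 2200))
        rec = HemoRecording(hbo=x, hbr=x, fs=11.0)
        y = bandpass(rec).hbo[0]
        assert abs(y[220:-220].mean()) < 1e-3

    def test_linearity(self, rng):
        x = rng.normal(size=(2, 500))
        y = rng.normal(size=(2, 500))
        rec = lambda d: HemoRecording(hbo=d, hbr=d, fs=11.0)
        lhs = bandpass(rec(2.0 * x + 3.0 * y)).hbo
        rhs = 2.0 * bandpass(rec(x)).hbo + 3.0 * bandpass(rec(y)).hbo
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_band_outside_nyquist_rejected(self):
        rec = HemoRecording(hbo=np.zeros((1, 100)), hbr=np.zeros((1, 100)), fs=11.0)
        with pytest.raises(ValueError, match="fs/2"):
            bandpass(rec, low=0.01, high=6.0)

    def test_length_preserved(self, rng):
        rec = HemoRecording(hbo=rng.normal(size=(3, 321)), hbr=rng.normal(size=(3, 321)), fs=11.0)
        assert bandpass(rec).hbo.shape == (3, 321)


# ---------------------------------------------------------------- segmentation
class TestSegmentTrials:
    def _recording(self, dur_s=400.0, fs=11.0):
        n = int(dur_s * fs)
        rng = np.random.default_rng(0)
        return HemoRecording(hbo=rng.normal(size=(16, n)), hbr=rng.normal(size=(16, n)), fs=fs)

    def test_paradigm_gives_20_trials_of_110_samples(self):
        rec = self._recording()
        events = paradigm_events(n_trials=20)
        ts = segment_trials(rec, events, task_window_s=10.0, rest_window_s=10.0)
        assert ts.n_trials == 20
        assert ts.n_samples == 110  # floor(10 s * 11 Hz)
        assert ts.n_channels == 32  # HbO + HbR planes
        assert np.bincount(ts.labels).tolist() == [10, 10]

    def test_empty_events(self):
        ts = segment_trials(self._recording(), [])
        assert ts.n_trials == 0

    def test_window_exceeding_recording_identifies_event(self):
        rec = self._recording(dur_s=30.0)
        with pytest.raises(ValueError, match="event 1"):
            segment_trials(rec, [(0.0, 1), (26.0, 0)], task_window_s=10.0, rest_window_s=10.0)

    def test_labels_carried_through(self):
        ts = segment_trials(self._recording(), [(0.0, "mi"), (20.0, "rest"), (40.0, 1)])
        assert ts.labels.tolist() == [1, 0, 1]


# --------------------------------------------------------------------- imaging
class TestCwtImage:
    def test_zero_signal_gives_zero_image(self):
        img = cwt_image(np.zeros((3, 64)), fs=11.0, n_scales=8, out_size=16)
        assert np.allclose(img.pixels, 0.0)

    def test_pure_tone_peaks_at_nearest_pseudofrequency(self):
        t = np.arange(2200) / 11.0
        sine = np.sin(2 * np.pi * 0.1 * t)[None, :]
        # 14 log-spaced scales put 0.1 Hz exactly on a grid row
        img = cwt_image(sine, fs=11.0, n_scales=14, out_size=14)
        row = np.unravel_index(np.argmax(img.pixels[0]), img.pixels[0].shape)[0]
        assert row == int(np.argmin(np.abs(img.freq_axis - 0.1)))

    def test_shape_contract_and_determinism(self, rng):
        x = rng.normal(size=(5, 165))
        a = cwt_image(x, fs=11.0, n_scales=8, out_size=24)
        b = cwt_image(x, fs=11.0, n_scales=8, out_size=24)
        assert a.pixels.shape == (5, 24, 24)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0

    def test_scales_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            cwt_image(np.zeros((1, 64)), fs=11.0, fmin=0.01, fmax=7.0)

    def test_agrees_with_pywavelets_oracle(self):
        """Scale profile of the frequency-domain CWT matches pywt.cwt where the
        wavelet support fits inside the record (wider scales are edge-dominated
        in any implementation)."""
        pywt = pytest.importorskip("pywt")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 6000))
        freqs = np.geomspace(0.2, 0.1, 6)  # pywt kernel lengths <= ~1800 samples
        scales = pywt.frequency2scale("cmor1.5-1.0", freqs / 11.0)
        ref, _ = pywt.cwt(x, scales, "cmor1.5-1.0", axis=-1, method="fft")
        mine = morlet_cwt(x, freqs, 11.0)
        sl = slice(1500, 4500)  # central region, away from both edges
        for i in range(len(freqs)):
            a, b = np.abs(ref[i, 0, sl]), np.abs(mine[0, i, sl])
            assert np.corrcoef(a, b)[0, 1] > 0.95


class TestStftImage:
    def test_pure_tone_peaks_at_nearest_fft_bin(self):
        t = np.arange(1000) / 250.0
        sine = np.sin(2 * np.pi * 10.0 * t)[None, :]
        img = stft_image(sine, fs=250.0, out_size=24)
        row = np.unravel_index(np.argmax(img.pixels[0]), img.pixels[0].shape)[0]
        assert img.freq_axis[row] == pytest.approx(10.0, abs=2.0)  # FFT bin width 2 Hz

    def test_zero_signal_zero_image(self):
        img = stft_image(np.zeros((2, 1000)), fs=250.0, out_size=16)
        assert np.allclose(img.pixels, 0.0)

    def test_overlap_changes_frame_count_about_twofold(self, rng):
        from scipy.signal import ShortTimeFFT, windows

        x = rng.normal(size=1000)
        win = windows.hann(125, sym=False)
        n0 = ShortTimeFFT(win, hop=125, fs=250.0).t(1000).size
        n5 = ShortTimeFFT(win, hop=63, fs=250.0).t(1000).size
        assert abs(n5 / n0 - 2.0) < 0.2

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            stft_image(np.zeros((1, 1000)), fs=250.0, band=(4.0, 200.0))
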
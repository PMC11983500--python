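"""Synthetic generator contracts: seeding, class structure, physical round
trips, and the documented signal model."""

import numpy as np
import pytest
from scipy import stats

from helpers import bandpower
from chtlm.containers import ConfigError, ExtinctionMatrix
from chtlm.preprocess import beer_lambert
from chtlm.synthetic import (
    SynthConfig,
    double_gamma_hrf,
    generate_eeg_subject,
    generate_fnirs_subject,
    hemo_to_raw_intensity,
    hrf_response,
    raw_trial_to_optical,
)


class TestSeedingContract:
    def test_same_config_same_seed_identical(self):
        cfg = SynthConfig(seed=5, trials_per_class=3)
        a = generate_fnirs_subject(cfg, "S1")
        b = generate_fnirs_subject(cfg, "S1")
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seeds_differ(self):
        a = generate_fnirs_subject(SynthConfig(seed=1, trials_per_class=3), "S1")
        b = generate_fnirs_subject(SynthConfig(seed=2, trials_per_class=3), "S1")
        assert not np.array_equal(a.data, b.data)

    def test_subjects_differ(self):
        cfg = SynthConfig(seed=1, trials_per_class=3)
        a = generate_fnirs_subject(cfg, "S1")
        b = generate_fnirs_subject(cfg, "S2")
        assert not np.array_equal(a.data, b.data)


class TestFnirsSignalModel:
    def test_mi_peak_matches_direct_convolution_oracle(self):
        cfg = SynthConfig(seed=3, trials_per_class=2, noise_sd=1e-9, effect_amp=1.0,
                          subject_gain_sd=0.0, subject_latency_sd=0.0)
        ts = generate_fnirs_subject(cfg, "S1")
        mi = ts.data[ts.labels == 1][0]
        # independent oracle: direct numerical convolution of the boxcar with
        # the double-gamma HRF, normalized to unit peak
        fs, n = cfg.fs_fnirs, ts.n_samples
        t = np.arange(n) / fs
        box = ((t >= 0) & (t < cfg.task_s)).astype(float)
        hrf = double_gamma_hrf(np.arange(0, 32, 1 / fs))
        resp = np.convolve(box, hrf)[:n]
        resp /= resp.max()
        assert mi[0].max() == pytest.approx(resp.max(), abs=1e-6)
        assert np.allclose(mi[0], resp, atol=1e-6)  # active HbO channel
        # HbR anticorrelation: -0.3 x HbO response
        n_ch = cfg.n_channels_fnirs
        assert np.allclose(mi[n_ch], -0.3 * resp, atol=1e-6)

    def test_rest_trials_have_no_task_component(self):
        cfg = SynthConfig(seed=3, trials_per_class=2, noise_sd=1e-9, effect_amp=1.0,
                          subject_gain_sd=0.0, subject_latency_sd=0.0)
        ts = generate_fnirs_subject(cfg, "S1")
        rest = ts.data[ts.labels == 0][0]
        assert np.abs(rest[0]).max() < 1e-6

    def test_zero_effect_classes_indistinguishable(self):
        cfg = SynthConfig(seed=9, trials_per_class=10, effect_amp=0.0)
        pvals = []
        for sid in ("S1", "S2", "S3", "S4"):
            ts = generate_fnirs_subject(cfg, sid)
            means = ts.data.mean(axis=(1, 2))
            _, p = stats.mannwhitneyu(means[ts.labels == 1], means[ts.labels == 0],
                                      alternative="two-sided")
            pvals.append(p)
        assert min(pvals) > 0.01  # no spurious class effect

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="noise_sd"):
            SynthConfig(noise_sd=0.0)
        with pytest.raises(ConfigError, match="trials_per_class"):
            SynthConfig(trials_per_class=0)
        with pytest.raises(ConfigError, match="effect_amp"):
            SynthConfig(effect_amp=-1.0)


class TestEegGenerator:
    def test_separable_classes_bandpower_oracle(self):
        cfg = SynthConfig(seed=4, trials_per_class=20, effect_amp=4.0, noise_sd=0.1,
                          subject_gain_sd=0.0)
        ts = generate_eeg_subject(cfg, "S1", ("left", "right"))
        # oracle: mu-band power difference between the two channel groups
        bp = bandpower(ts.data, cfg.fs_eeg, 8, 13)
        half = cfg.n_channels_eeg // 2
        feat = bp[:, :half].mean(axis=1) - bp[:, half:].mean(axis=1)
        pred = (feat < np.median(feat)).astype(int)
        acc = max(np.mean(pred == ts.labels), 1 - np.mean(pred == ts.labels))
        assert acc == 1.0

    def test_zero_modulation_is_chance(self):
        cfg = SynthConfig(seed=4, trials_per_class=20, effect_amp=0.0)
        ts = generate_eeg_subject(cfg, "S1", ("left", "right"))
        bp = bandpower(ts.data, cfg.fs_eeg, 8, 13)
        half = cfg.n_channels_eeg // 2
        feat = bp[:, :half].mean(axis=1) - bp[:, half:].mean(axis=1)
        pred = (feat > 0).astype(int)
        acc = np.mean(pred == ts.labels)
        assert 0.35 <= acc <= 0.65

    def test_four_classes_equal_counts(self):
        cfg = SynthConfig(seed=2, trials_per_class=6)
        ts = generate_eeg_subject(cfg, "S1", ("left", "right", "foot", "tongue"))
        assert sorted(np.bincount(ts.labels)) == [6, 6, 6, 6]
        assert len(np.unique(ts.labels)) == 4

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="elbow"):
            generate_eeg_subject(SynthConfig(seed=1), "S1", ("left", "elbow"))


class TestRawIntensityRoundTrip:
    def test_zero_concentration_gives_baseline_intensity(self):
        cfg = SynthConfig(seed=1, trials_per_class=1, effect_amp=0.0, noise_sd=1e-12)
        ts = generate_fnirs_subject(cfg, "S1")
        ts.data[:] = 0.0
        raw = hemo_to_raw_intensity(ts, i0=2.5)
        assert np.allclose(raw.data, 2.5)

    def test_round_trip_identity(self):
        cfg = SynthConfig(seed=7, trials_per_class=3)
        ts = generate_fnirs_subject(cfg, "S1")
        raw = hemo_to_raw_intensity(ts)
        for k in range(ts.n_trials):
            opt = raw_trial_to_optical(raw, k)
            hemo = beer_lambert(opt, i0=1.0)
            rec = np.concatenate([hemo.hbo, hemo.hbr], axis=0)
            assert np.abs(rec - ts.data[k]).max() < 1e-8

    def test_unit_concentration_column_hand_check(self):
        # single sample with (dHbO, dHbR) = (1, 0): dA per wavelength equals
        # (d/10)*dpf*eps[:, 0], by hand matrix multiplication
        eps = ExtinctionMatrix(np.array([[0.5, 1.1], [1.2, 0.8]]))
        from chtlm.containers import TrialSet

        n_ch = 1
        data = np.zeros((1, 2 * n_ch, 1))
        data[0, 0, 0] = 1.0  # HbO plane
        ts = TrialSet(data=data, labels=[1], subject_id="S1", modality="fnirs-hemo",
                      fs=11.0, channel_names=["CH01_HbO", "CH01_HbR"])
        raw = hemo_to_raw_intensity(ts, eps=eps, dpf=(6.0, 6.0), d_mm=30.0, i0=1.0)
        da = -np.log10(raw.data[0, :, 0])  # per wavelength
        expected = 3.0 * 6.0 * eps.eps[:, 0]  # (d/10 cm)*dpf*eps column for HbO2
        assert np.allclose(da, expected, atol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="singular|ill-conditioned"):
            ExtinctionMatrix(np.array([[1.0, 2.0], [2.0, 4.0]]))


def test_hrf_response_unit_peak_and_latency_shift():
    r0 = hrf_response(165, 11.0, 0.0, 15.0)
    r2 = hrf_response(165, 11.0, 2.0, 15.0)
    assert r0.max() == pytest.approx(1.0)
    assert np.argmax(r2) > np.argmax(r0)
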
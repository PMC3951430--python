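"""Referencing, notch, Welch PSD, band normalization and group statistics."""

import numpy as np
import pytest

from stnpipe import spectra as sp
from stnpipe.synthetic import SignalTruth, gen_field_potentials

FS = 1000.0


def sine(freq, duration=10.0, amp=1.0, fs=FS, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestBipolar:
    def test_identical_channels_cancel(self):
        a = sine(20)
        assert np.allclose(sp.bipolar_derive(a, a), 0.0)

    def test_zero_reference_is_identity(self):
        a = sine(20)
        assert np.allclose(sp.bipolar_derive(a, np.zeros_like(a)), a)

    def test_common_mode_line_noise_cancelled(self):
        # identical 50 Hz on both channels, distinct physiological content
        line = sine(50, amp=2.0)
        a = line + sine(10, amp=0.5)
        b = line + sine(15, amp=0.5)
        out = sp.bipolar_derive(a, b)
        freqs, psd_out = sp.welch_psd(out, FS)
        _, psd_in = sp.welch_psd(a, FS)
        line_bin = np.argmin(np.abs(freqs - 50))
        attenuation_db = 10 * np.log10(psd_out[line_bin] / psd_in[line_bin] + 1e-300)
        assert attenuation_db < -60


class TestNotch:
    def test_50hz_attenuated_30db(self):
        x = sine(50, duration=20)
        y = sp.notch_50(x, FS)
        assert 20 * np.log10(rms(y[1000:-1000]) / rms(x)) <= -30

    def test_10hz_essentially_untouched(self):
        x = sine(10, duration=20)
        y = sp.notch_50(x, FS)
        assert abs(20 * np.log10(rms(y[1000:-1000]) / rms(x[1000:-1000]))) <= 1

    def test_dc_unchanged(self):
        x = np.full(5000, 3.0)
        assert np.allclose(sp.notch_50(x, FS), 3.0, atol=1e-6)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            sp.notch_50(np.zeros(100), fs=90.0)


class TestWelch:
    def test_white_noise_power_matches_variance(self, rng):
        x = rng.standard_normal(int(60 * FS))
        freqs, psd = sp.welch_psd(x, FS)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_sinusoid_peak_at_32hz(self):
        freqs, psd = sp.welch_psd(sine(32), FS)
        assert freqs[np.argmax(psd)] == pytest.approx(32.0, abs=0.5)

    def test_quadratic_amplitude_scaling(self):
        f1, p1 = sp.welch_psd(sine(20), FS)
        _, p2 = sp.welch_psd(sine(20, amp=2.0), FS)
        assert np.allclose(p2, 4 * p1, rtol=1e-9)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sp.welch_psd(np.zeros(100), FS, segment_s=2.0)


class TestNormalizePSD:
    def test_in_band_sum_is_one(self, rng):
        freqs, psd = sp.welch_psd(rng.standard_normal(20000), FS)
        npsd = sp.normalize_psd(freqs, psd)
        in_band = (freqs >= 1) & (freqs <= 80)
        assert npsd[in_band].sum() == pytest.approx(1.0, abs=1e-9)

    def test_flat_psd_equal_bins(self):
        freqs = np.arange(0, 101, 1.0)
        npsd = sp.normalize_psd(freqs, np.ones_like(freqs))
        in_band = (freqs >= 1) & (freqs <= 80)
        assert np.allclose(npsd[in_band], 1.0 / in_band.sum())

    def test_two_equal_lines_half_each(self):
        x = sine(10) + sine(30)
        freqs, psd = sp.welch_psd(x, FS)
        npsd = sp.normalize_psd(freqs, psd)
        for f in (10.0, 30.0):
            window = (freqs > f - 2) & (freqs < f + 2)
            assert npsd[window].sum() == pytest.approx(0.5, abs=0.01)


class TestFrequencyWeighting:
    def test_one_over_f_becomes_flat(self):
        freqs = np.arange(1.0, 81.0)
        spec = (1.0 / freqs)[:, None] * np.ones((1, 5))
        disp, flags = sp.frequency_weighted_tf(freqs, spec)
        assert np.allclose(disp, disp[0, 0])
        assert not flags.any()

    def test_white_input_linear_ramp(self):
        freqs = np.arange(1.0, 81.0)
        disp, _ = sp.frequency_weighted_tf(freqs, np.ones((80, 3)))
        assert np.allclose(disp[:, 0], freqs / freqs.sum())

    def test_zero_column_flagged(self):
        freqs = np.arange(1.0, 11.0)
        spec = np.ones((10, 2))
        spec[:, 1] = 0.0
        disp, flags = sp.frequency_weighted_tf(freqs, spec)
        assert flags.tolist() == [False, True]
        assert np.allclose(disp[:, 1], 0.0)


class TestBandPower:
    def test_32hz_line_lands_in_high_beta(self):
        freqs, psd = sp.welch_psd(sine(32, duration=20), FS)
        npsd = sp.normalize_psd(freqs, psd)
        bands = sp.band_relative_power(freqs, npsd)
        assert bands["high_beta"] > 0.99

    def test_flat_spectrum_power_proportional_to_width(self):
        freqs = np.arange(0.0, 101.0, 1.0)
        npsd = sp.normalize_psd(freqs, np.ones_like(freqs))
        bands = sp.band_relative_power(freqs, npsd)
        # delta spans 3 bins (1-3 Hz), theta 4 bins (4-7 Hz)
        assert bands["theta"] / bands["delta"] == pytest.approx(4 / 3)

    def test_line_bin_excluded_from_gamma(self):
        freqs = np.arange(0.0, 101.0, 1.0)
        psd = np.zeros_like(freqs)
        psd[freqs == 50.0] = 1.0
        psd[freqs == 40.0] = 1.0
        npsd = sp.normalize_psd(freqs, psd)
        bands = sp.band_relative_power(freqs, npsd)
        assert bands["low_gamma"] == pytest.approx(0.5)  # only the 40 Hz bin
        assert bands["high_gamma"] == 0.0

    def test_band_power_amplitude_invariant(self, rng):
        x = rng.standard_normal(30000) + sine(32, duration=30)
        out = []
        for scale in (1.0, 7.3):
            freqs, psd = sp.welch_psd(scale * x, FS)
            npsd = sp.normalize_psd(freqs, psd)
            out.append(sp.band_relative_power(freqs, npsd))
        for band in out[0]:
            assert out[0][band] == pytest.approx(out[1][band], rel=1e-9)

    def test_overlapping_scheme_rejected(self):
        with pytest.raises(ValueError):
            sp.BandScheme((("a", 1, 10), ("b", 5, 20)))


class TestCompareBandPower:
    def test_identical_groups_not_significant(self):
        obs = [{b: 0.1 * (i + 1) for b in sp.BandScheme().names} for i in range(6)]
        out = sp.compare_band_power(obs, list(obs))
        assert (out["p"] == 1.0).all()
        assert not out["significant"].any()

    def test_complete_separation_six_vs_six_flagged(self):
        names = sp.BandScheme().names
        a = [{b: 1.0 + i * 0.01 for b in names} for i in range(6)]
        b = [{b: 2.0 + i * 0.01 for b in names} for i in range(6)]
        out = sp.compare_band_power(a, b)
        assert np.allclose(out["p"], 2 / 924)
        assert out["significant"].all()  # 2/924 < 0.05/7

    def test_planted_high_beta_elevation_only_flagged(self):
        # lesioned-group signals carry a 32 Hz oscillation; controls do not
        flagged_high_beta = 0
        for seed in range(20):
            groups = {}
            for label, amp in (("pd", 1.2), ("ctl", 0.0)):
                obs = []
                for ch in range(6):
                    truth = SignalTruth(
                        duration_s=20.0,
                        oscillation_amplitude=amp,
                        noise_scale=1.0,
                        seed=1000 * seed + ch + (0 if label == "pd" else 500),
                    )
                    rec, _ = gen_field_potentials(truth, n_channels=1)
                    res = sp.analyze_record(rec)
                    obs.append(res.band_power["ch0"])
                groups[label] = obs
            out = sp.compare_band_power(groups["pd"], groups["ctl"]).set_index("band")
            if out.loc["high_beta", "significant"]:
                flagged_high_beta += 1
            # the oscillation raises relative high-beta power; because the
            # spectrum is normalized to total 1-80 Hz power, any other band
            # that separates can only do so in the opposite direction
            assert out.loc["high_beta", "median_a"] > out.loc["high_beta", "median_b"]
            others = out.drop(index="high_beta")
            sig_others = others[others["significant"]]
            assert (sig_others["median_a"] < sig_others["median_b"]).all()
        assert flagged_high_beta == 20


def test_high_beta_peak_stays_out_of_gamma():
    for seed in range(5):
        truth = SignalTruth(duration_s=20.0, oscillation_amplitude=1.0, noise_scale=1.0, seed=seed)
        rec, _ = gen_field_potentials(truth, n_channels=1)
        res = sp.analyze_record(rec)
        npsd = res.normalized["ch0"]
        in_band = (res.freqs >= 1) & (res.freqs <= 80)
        peak = res.freqs[in_band][np.argmax(npsd[in_band])]
        assert 25 <= peak <= 35


def test_signal_record_roundtrip(tmp_path):
    truth = SignalTruth(duration_s=11.0, seed=8)
    rec, _ = gen_field_potentials(truth, n_channels=2)
    rec.write_csv(tmp_path / "sig.csv")
    back = sp.SignalRecord.read_csv(tmp_path / "sig.csv")
    assert back.fs_hz == rec.fs_hz
    assert np.allclose(back.channels["ch1"], rec.channels["ch1"])
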
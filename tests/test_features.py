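"""Spectra, COP, per-channel statistics, and feature-vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gaitfusion import (
    FeatureOptions,
    SensorLayout,
    assemble_features,
    band_spectral_features,
    cop_trajectory,
    feature_names,
    global_biomech_features,
    imu_freq_features,
    imu_time_features,
    pressure_time_features,
    rom_and_symmetry,
    spectrum,
)
from gaitfusion.features import GAIT_BAND
from gaitfusion.preprocessing import GaitWindow

FS = 100.0


def _tone(freq, n=128, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestSpectrum:
    def test_bin_width_is_0p195_hz(self):
        spec = spectrum(np.zeros(128))
        assert spec.df == pytest.approx(100.0 / 512)
        assert spec.df == pytest.approx(0.195, abs=5e-4)

    def test_all_zero_window(self):
        assert np.all(spectrum(np.zeros(128)).amps == 0.0)

    def test_matches_direct_sum_dft_oracle(self):
        # O(N^2) DFT on 8 points, no padding
        rng = np.random.default_rng(1)
        x = rng.standard_normal(8)
        tapered = x * np.hanning(8)
        n = 8
        direct = np.array([
            abs(sum(tapered[i] * np.exp(-2j * np.pi * k * i / n)
                    for i in range(n)))
            for k in range(n // 2 + 1)
        ])
        ours = spectrum(x, n_fft=8).amps
        np.testing.assert_allclose(ours, direct, rtol=1e-10, atol=1e-12)

    def test_parseval_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(128)
        tapered = x * np.hanning(128)
        full = np.fft.fft(tapered, 512)
        assert np.sum(np.abs(full) ** 2) / 512 == pytest.approx(
            np.sum(tapered**2), rel=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            spectrum(np.array([1.0, np.nan]))


class TestBandFeatures:
    def test_pure_tone_dominant_frequency(self):
        spec = spectrum(_tone(2.0))
        f_dom, _, _ = band_spectral_features(spec)
        assert f_dom == pytest.approx(2.0, abs=spec.df / 2 + 1e-9)

    def test_single_tone_centroid_near_tone(self):
        spec = spectrum(_tone(5.0))
        _, centroid, _ = band_spectral_features(spec)
        assert centroid == pytest.approx(5.0, abs=0.8)  # leakage tolerance

    def test_flat_spectrum_prominence_one(self):
        from gaitfusion.features import Spectrum
        freqs = np.fft.rfftfreq(512, d=1 / FS)
        spec = Spectrum(freqs=freqs, amps=np.ones_like(freqs), df=100 / 512)
        _, _, prom = band_spectral_features(spec)
        assert prom == pytest.approx(1.0)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_spectral_features(spectrum(_tone(2.0)), band=(30.0, 20.0))


class TestCOP:
    def test_single_support_limit(self, layout):
        coords = layout.coords12()
        for j in [0, 5, 7, 11]:
            p = np.zeros((12, 10))
            p[j] = 100.0
            x, y = cop_trajectory(p, layout)
            np.testing.assert_allclose(x, coords[j, 0])
            np.testing.assert_allclose(y, coords[j, 1])

    def test_equal_loading_gives_layout_centroid(self, layout):
        p = np.full((12, 4), 50.0)
        x, y = cop_trajectory(p, layout)
        centroid = layout.coords12().mean(axis=0)
        np.testing.assert_allclose(x, centroid[0])
        np.testing.assert_allclose(y, centroid[1])

    @settings(derandomize=True, max_examples=30)
    @given(hnp.arrays(np.float64, (12, 6),
                      elements=st.floats(min_value=0.1, max_value=500.0)))
    def test_scale_invariance(self, p):
        layout = SensorLayout()
        x1, y1 = cop_trajectory(p, layout, floor=0.0)
        x2, y2 = cop_trajectory(2.0 * p, layout, floor=0.0)
        np.testing.assert_allclose(x1, x2, rtol=1e-9)
        np.testing.assert_allclose(y1, y2, rtol=1e-9)

    def test_unloaded_frames_flagged_not_fabricated(self, layout):
        p = np.zeros((12, 5))
        p[0, 2] = 100.0
        x, y = cop_trajectory(p, layout)
        assert np.isfinite(x[2])
        assert np.isnan(x[[0, 1, 3, 4]]).all()


class TestChannelStats:
    def test_constant_pressure_window(self):
        f = pressure_time_features(np.full(128, 7.0))
        names = dict(zip(
            ("max", "min", "mean", "rms", "abs_mean", "var", "sd", "ptp",
             "iqr", "skew", "kurtosis", "zcr", "energy", "crest",
             "contact_ratio"), f))
        assert names["sd"] == 0.0
        assert names["ptp"] == 0.0
        assert names["zcr"] == 0.0
        assert len(f) == 15

    def test_symmetric_window_zero_skewness(self):
        sym = np.sin(2 * np.pi * 2 * np.arange(128) / 128)
        assert imu_time_features(sym)[9] == pytest.approx(0.0, abs=1e-9)

    def test_imu_time_feature_count_and_constant_window(self):
        f = imu_time_features(np.full(128, -3.0))
        assert len(f) == 14
        # variance, sd, ptp, iqr all zero
        assert f[5] == f[6] == f[7] == f[8] == 0.0

    def test_imu_stats_match_naive_recomputation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(128)
        f = imu_time_features(x)
        from scipy import stats as sps
        q1, q3 = np.percentile(x, [25, 75])
        expected = [x.max(), x.min(), x.mean(), np.sqrt(np.mean(x**2)),
                    np.mean(np.abs(x)), x.var(), x.std(), x.max() - x.min(),
                    q3 - q1, sps.skew(x), sps.kurtosis(x)]
        np.testing.assert_allclose(f[:11], expected, rtol=1e-10)
        assert f[12] == pytest.approx(np.mean(x**2))
        assert f[13] == pytest.approx(np.max(np.abs(x))
                                      / np.sqrt(np.mean(x**2)))


class TestImuFreqFeatures:
    def test_count_is_10(self):
        assert len(imu_freq_features(_tone(3.0))) == 10

    def test_single_tone_has_small_bandwidth(self):
        f = imu_freq_features(_tone(4.0))
        bandwidth = f[9]
        assert bandwidth < 1.0  # concentrated spectrum

    def test_band_energy_ratios_partition_unity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(128)
        f = imu_freq_features(x)
        assert f[5] + f[6] + f[7] == pytest.approx(1.0, abs=1e-9)

    def test_flat_amplitude_spectrum_zero_amp_sd(self):
        # silent signal: degenerate flat (all-zero) spectrum
        f = imu_freq_features(np.zeros(128))
        assert f[4] == 0.0


class TestGlobalAndAddons:
    def _window(self, pressure, euler=None):
        if euler is None:
            euler = np.zeros((12, pressure.shape[1]))
        return GaitWindow(pressure=pressure, euler=euler, label="walking",
                          start=0)

    def test_symmetric_loading_zero_symmetry_index(self, layout):
        p = np.full((12, 128), 40.0)
        g = global_biomech_features(self._window(p), layout)
        assert g[5] == pytest.approx(0.0)  # load symmetry
        assert g[4] == pytest.approx(1.0)  # stance ratio: always loaded
        assert g[3] == pytest.approx(1.0)  # dual support: both feet loaded

    def test_walking_window_dual_support_plausible(self, walking_recording,
                                                   layout):
        g = global_biomech_features(
            walking_recording.pressure[:, :6000], layout)
        assert 0.10 <= g[3] <= 0.20
        assert abs(g[4] - 0.60) < 0.05

    def test_running_window_dual_support_zero(self, running_recording,
                                              layout):
        g = global_biomech_features(
            running_recording.pressure[:, :6000], layout)
        assert g[3] == 0.0

    def test_rom_and_thigh_xcorr(self):
        t = np.arange(128)
        euler = np.zeros((4, 3, 128))
        euler[0, 0] = 30 * np.sin(2 * np.pi * t / 64)
        euler[1, 0] = 30 * np.sin(2 * np.pi * t / 64 + np.pi)  # anti-phase
        w = GaitWindow(pressure=np.zeros((12, 128)),
                       euler=euler.reshape(12, 128), label="walking", start=0)
        out = rom_and_symmetry(w)
        assert out[0] == pytest.approx(60.0, rel=1e-3)
        assert out[4] == pytest.approx(-1.0, abs=1e-9)

    def test_identical_thigh_sequences_correlate_plus_one(self):
        t = np.arange(128)
        euler = np.zeros((4, 3, 128))
        euler[0, 0] = euler[1, 0] = np.sin(t / 5.0)
        w = GaitWindow(pressure=np.zeros((12, 128)),
                       euler=euler.reshape(12, 128), label="walking", start=0)
        assert rom_and_symmetry(w)[4] == pytest.approx(1.0)

    def test_constant_angles_rom_zero_xcorr_undefined(self):
        w = GaitWindow(pressure=np.zeros((12, 128)),
                       euler=np.full((12, 128), 5.0), label="sitting", start=0)
        out = rom_and_symmetry(w)
        assert np.all(out[:4] == 0.0)
        assert np.isnan(out[4])


class TestAssembly:
    def test_dimensionalities_222_288_510(self, walking_windows, layout):
        w = walking_windows[0]
        fused = assemble_features(w, layout, FeatureOptions(modality="fused"))
        pressure = assemble_features(w, layout,
                                     FeatureOptions(modality="pressure"))
        imu = assemble_features(w, layout, FeatureOptions(modality="imu"))
        assert len(pressure.values) == 222
        assert len(imu.values) == 288
        assert len(fused.values) == 510
        assert np.all(np.isfinite(fused.values))

    def test_addons_appended_when_enabled(self, walking_windows, layout):
        w = walking_windows[0]
        v = assemble_features(w, layout,
                              FeatureOptions(modality="fused",
                                             include_addons=True))
        assert len(v.values) == 515

    def test_names_unique_stable_and_aligned(self, walking_windows, layout):
        names1 = feature_names(FeatureOptions(modality="fused"))
        names2 = feature_names(FeatureOptions(modality="fused"))
        assert names1 == names2
        assert len(set(names1)) == len(names1) == 510
        v = assemble_features(walking_windows[0], layout)
        assert v.names == names1
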
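import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semgkit.features import (
    FeatureMatrix,
    Spectrum,
    build_feature_matrix,
    extract_features,
    feature_names,
    mav,
    mdf,
    mnf,
    power_spectrum,
    rms,
)
from semgkit.signal_io import Window, segment
from semgkit.wpt import wp_decompose

finite_seqs = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False), min_size=1, max_size=64
)


class TestAmplitudeFeatures:
    @pytest.mark.parametrize("x,expected", [
        ([1, -1, 1, -1], 1.0),
        ([0, 0, 0], 0.0),
        ([3, -4], 3.5),
    ])
    def test_mav_examples(self, x, expected):
        assert mav(np.array(x, dtype=float)) == pytest.approx(expected)

    @pytest.mark.parametrize("x,expected", [
        ([1, -1, 1, -1], 1.0),
        ([3, -4], np.sqrt(12.5)),
        ([0], 0.0),
    ])
    def test_rms_examples(self, x, expected):
        assert rms(np.array(x, dtype=float)) == pytest.approx(expected)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            mav(np.array([]))
        with pytest.raises(ValueError):
            rms(np.array([]))

    @given(finite_seqs)
    @settings(max_examples=200, deadline=None)
    def test_mav_never_exceeds_rms(self, xs):
        """Power-mean inequality: mean |x| <= sqrt(mean x^2)."""
        x = np.array(xs)
        assert mav(x) <= rms(x) + 1e-12 * (1 + rms(x))

    @given(finite_seqs, st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, xs, a):
        x = np.array(xs)
        assert mav(a * x) == pytest.approx(abs(a) * mav(x), rel=1e-9, abs=1e-9)
        assert rms(a * x) == pytest.approx(abs(a) * rms(x), rel=1e-9, abs=1e-9)


class TestPowerSpectrum:
    def test_on_bin_cosine_concentrates(self):
        n, rate, j0 = 128, 500.0, 10
        f0 = j0 * rate / n
        x = np.cos(2 * np.pi * f0 * np.arange(n) / rate)
        s = power_spectrum(x, rate)
        assert np.argmax(s.power) == j0
        others = np.delete(s.power, j0)
        assert others.max() < 1e-18 * s.power[j0] + 1e-12

    def test_zero_signal(self):
        s = power_spectrum(np.zeros(16), 500.0)
        assert np.all(s.power == 0)

    def test_parseval_identity(self, rng):
        x = rng.normal(size=101)
        s = power_spectrum(x, 500.0)
        two_sided = 2 * np.sum(s.power) - s.power[0]
        if x.size % 2 == 0:
            two_sided -= s.power[-1]
        assert two_sided == pytest.approx(x.size * np.sum(x**2), rel=1e-10)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([1.0]), 500.0)


class TestSpectralFeatures:
    def test_mnf_examples(self):
        assert mnf(Spectrum(freqs=[0, 10, 20], power=[0, 1, 1])) == pytest.approx(15.0)
        assert mnf(Spectrum(freqs=[0, 10, 20], power=[0, 0, 5])) == pytest.approx(20.0)

    def test_mnf_zero_power_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero-power"):
            assert mnf(Spectrum(freqs=[0, 10], power=[0, 0])) == 0.0

    def test_mdf_cumulative_example(self):
        assert mdf(Spectrum(freqs=[0, 10, 20], power=[1, 2, 1])) == pytest.approx(10.0)

    def test_mdf_point_mass_at_first_bin(self):
        assert mdf(Spectrum(freqs=[0, 10, 20], power=[4, 0, 0])) == pytest.approx(0.0)

    def test_mdf_tie_takes_smallest_index(self):
        assert mdf(Spectrum(freqs=[0, 10, 20], power=[0, 1, 1])) == pytest.approx(10.0)

    def test_mdf_zero_power_warns(self):
        with pytest.warns(UserWarning, match="zero-power"):
            assert mdf(Spectrum(freqs=[0, 10], power=[0, 0])) == 0.0

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=32),
           st.floats(0.1, 50, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_mnf_mdf_scale_invariant(self, powers, a):
        s = Spectrum(freqs=np.arange(len(powers), dtype=float), power=np.array(powers))
        sa = Spectrum(freqs=s.freqs, power=a * s.power)
        assert mnf(sa) == pytest.approx(mnf(s), rel=1e-9)
        assert mdf(sa) == mdf(s)

    def test_sinusoid_mnf_mdf_within_one_bin(self):
        n, rate = 256, 500.0
        f0 = 40 * rate / n  # on a bin
        x = np.cos(2 * np.pi * f0 * np.arange(n) / rate)
        s = power_spectrum(x, rate)
        bin_width = rate / n
        assert abs(mnf(s) - f0) <= bin_width
        assert abs(mdf(s) - f0) <= bin_width

    def test_spectrum_invariants_enforced(self):
        with pytest.raises(ValueError):
            Spectrum(freqs=[10, 0], power=[1, 1])
        with pytest.raises(ValueError):
            Spectrum(freqs=[0, 10], power=[1, -1])


class TestExtractFeatures:
    def _window(self, samples, rate=500.0):
        return Window(samples=samples, label="CY", subject="s1", trial=0,
                      start_index=0, rate=rate)

    def test_two_channel_level3_yields_64(self, rng):
        w = self._window(rng.normal(size=(400, 2)))
        assert extract_features(w, "dmey", 3).shape == (64,)

    def test_one_channel_level1_yields_8(self, rng):
        w = self._window(rng.normal(size=(400, 1)))
        assert extract_features(w, "db4", 1).shape == (8,)

    def test_zero_window_features(self):
        w = self._window(np.zeros((400, 2)))
        row = extract_features(w, "db4", 3)
        assert np.all(row == 0.0)

    def test_feature_name_order(self):
        names = feature_names(2, 3)
        assert len(names) == 64
        assert names[0] == "ch1_band0_MAV"
        assert names[3] == "ch1_band0_MDF"
        assert names[4] == "ch1_band1_MAV"
        assert names[32] == "ch2_band0_MAV"

    def test_subband_energy_recovers_window_energy(self, rng):
        """sum over bands of RMS^2 * length equals the window energy
        (orthonormal basis, periodization) — the Parseval link."""
        x = rng.normal(size=(400, 1))
        w = self._window(x)
        s = wp_decompose(x[:, 0], "db4", 3)
        total = sum(rms(c) ** 2 * c.size for c in s.coeffs)
        assert total == pytest.approx(np.sum(x**2), rel=1e-10)

    def test_reconstructed_mode_uses_full_rate_axis(self, rng):
        w = self._window(rng.normal(size=(400, 1)))
        row_c = extract_features(w, "db4", 3, on_reconstructed=False)
        row_r = extract_features(w, "db4", 3, on_reconstructed=True)
        # amplitude features identical (same coefficients); spectral differ
        assert np.allclose(row_c[0::4], row_r[0::4])
        assert not np.allclose(row_c[2::4], row_r[2::4])


class TestFeatureMatrix:
    def test_build_and_csv_roundtrip(self, tmp_path, small_trial_set):
        windows = []
        for rec in small_trial_set[:4]:
            windows.extend(segment(rec, 400))
        fm = build_feature_matrix(windows, basis="db4", level=3)
        assert fm.values.shape == (len(windows), 64)
        p = tmp_path / "f.csv"
        fm.to_csv(p)
        back = FeatureMatrix.from_csv(p)
        assert back.feature_names == fm.feature_names
        assert np.array_equal(back.values, fm.values)
        assert np.array_equal(back.labels, fm.labels)
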
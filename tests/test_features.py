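"""Windowed feature extraction against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_features

from accelval.errors import UndefinedStatisticError
from accelval.features import (
    FEATURE_NAMES,
    Window,
    WindowSpec,
    angle_stats,
    axis_correlations,
    distribution_stats,
    dominant_frequency,
    extract_features,
    featurize,
    power_fraction_band,
    segment_windows,
    vector_magnitude,
    vm_spectrum,
)
from accelval.signal_io import AccelRecording


def make_window(samples, rate=10.0):
    return Window(
        samples=np.asarray(samples, float),
        sampling_rate=rate,
        window_index=0,
        device_id="dev",
        start_time=0.0,
    )


def tone_window(freq, rate=10.0, seconds=16, amp=1.0, offset=2.0):
    """VM-modulating tone riding on a static offset, on the x axis."""
    n = int(rate * seconds)
    t = np.arange(n) / rate
    samples = np.zeros((n, 3))
    samples[:, 0] = offset + amp * np.sin(2 * np.pi * freq * t)
    return make_window(samples, rate)


@pytest.mark.parametrize(
    "xyz,expected", [((3, 4, 0), 5.0), ((0, 0, 0), 0.0), ((1, 2, 2), 3.0)]
)
def test_vector_magnitude(xyz, expected):
    assert vector_magnitude(*xyz) == expected


class TestSegmentation:
    def test_window_counts(self, rng):
        rec = AccelRecording("d", 10.0, rng.normal(size=(3000, 3)))  # 300 s
        assert len(segment_windows(rec, WindowSpec(16.0))) == 18
        assert len(segment_windows(rec, WindowSpec(1.0))) == 300

    def test_short_recording_warns_and_returns_empty(self, rng):
        rec = AccelRecording("d", 10.0, rng.normal(size=(100, 3)))  # 10 s
        with pytest.warns(UserWarning):
            assert segment_windows(rec, WindowSpec(16.0)) == []
        with pytest.warns(UserWarning):
            assert featurize(rec, WindowSpec(16.0)).empty

    def test_windows_carry_metadata_and_are_contiguous(self, rng):
        rec = AccelRecording("watch", 10.0, rng.normal(size=(500, 3)))
        wins = segment_windows(rec, WindowSpec(2.0))
        assert [w.window_index for w in wins] == list(range(25))
        assert all(w.device_id == "watch" for w in wins)
        np.testing.assert_array_equal(
            np.concatenate([w.samples for w in wins]), rec.samples
        )


class TestSpectrum:
    def test_pure_tone_dominant_bin(self):
        w = tone_window(2.0, rate=10.0, seconds=16)
        vm = np.linalg.norm(w.samples, axis=1)
        freqs, mod = vm_spectrum(vm, 10.0)
        assert freqs[np.argmax(mod)] == pytest.approx(2.0)

    def test_constant_series_all_zero(self):
        freqs, mod = vm_spectrum(np.full(64, 3.3), 10.0)
        np.testing.assert_allclose(mod, 0.0, atol=1e-9)

    def test_energy_identity_against_naive_dft(self, rng):
        # the one-sided moduli must carry exactly the tapered series' energy
        vm = rng.normal(2.0, 0.5, size=33)
        freqs, mod = vm_spectrum(vm, 10.0)
        n = len(vm)
        taper = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
        d = (vm - vm.mean()) * taper
        full = np.abs(np.fft.fft(d)) ** 2
        one_sided = full[0] + 2 * np.sum(mod[: (n - 1) // 2] ** 2)
        if n % 2 == 0:
            one_sided -= mod[-1] ** 2  # Nyquist bin is not doubled
        assert np.sum(full) == pytest.approx(one_sided, rel=1e-9)
        assert np.sum(full) == pytest.approx(n * np.sum(d**2), rel=1e-9)

    def test_band_fraction_examples(self):
        for freq, bound, cmp in ((1.5, 0.99, "ge"), (3.5, 0.01, "le")):
            w = tone_window(freq, rate=10.0, seconds=16)
            vm = np.linalg.norm(w.samples, axis=1)
            frac = power_fraction_band(*vm_spectrum(vm, 10.0))
            assert frac >= bound if cmp == "ge" else frac <= bound

    def test_two_equal_tones_split_band_mass(self):
        rate, n = 20.0, 320
        t = np.arange(n) / rate
        vm = 3 + np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 4.0 * t)
        frac = power_fraction_band(*vm_spectrum(vm, rate))
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_dominant_frequency_and_amplitude_ordering(self):
        rate, n = 20.0, 320
        t = np.arange(n) / rate
        vm = 2 * np.sin(2 * np.pi * 1.0 * t) + 1 * np.sin(2 * np.pi * 3.0 * t)
        df, fpdf = dominant_frequency(*vm_spectrum(vm, rate))
        assert df == pytest.approx(1.0)
        assert 0 < fpdf <= 1

    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.array([1.0, 2.0, 3.0])
        moduli = np.array([5.0, 5.0, 1.0])
        df, _ = dominant_frequency(freqs, moduli)
        assert df == 1.0

    def test_zero_spectrum_returns_zeros(self):
        assert dominant_frequency(np.array([1.0]), np.array([0.0])) == (0.0, 0.0)


class TestAngleStats:
    def test_pure_x_gives_half_pi(self):
        mean, sd = angle_stats(np.tile([2.0, 0.0, 0.0], (10, 1)))
        assert mean == pytest.approx(np.pi / 2)
        assert sd == pytest.approx(0.0)

    def test_zero_x_gives_zero(self):
        mean, _ = angle_stats(np.tile([0.0, 1.0, 1.0], (10, 1)))
        assert mean == pytest.approx(0.0)

    def test_alternating_axes(self):
        samples = np.array([[1.0, 0, 0], [0, 1.0, 0]] * 5)
        mean, sd = angle_stats(samples)
        assert mean == pytest.approx(np.pi / 4)
        assert sd == pytest.approx(np.std([np.pi / 2, 0.0] * 5, ddof=1))

    def test_all_zero_vm_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            angle_stats(np.zeros((5, 3)))


class TestDistributionStats:
    def test_constant_vm(self):
        mvm, sdvm, cov, skew, kurt, entropy, cv = distribution_stats(np.full(16, 2.5))
        assert (mvm, sdvm, cov, cv, entropy) == (2.5, 0.0, 0.0, 0.0, 0.0)
        assert skew == 0.0 and kurt == 0.0

    def test_symmetric_series_has_zero_skewness(self):
        _, _, _, skew, _, _, _ = distribution_stats(np.array([1.0, 2.0, 3.0] * 8))
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_series(self):
        mvm, sdvm, cov, _, _, _, cv = distribution_stats(np.array([1.0, 1.0, 1.0, 5.0]))
        assert mvm == pytest.approx(2.0)
        assert sdvm == pytest.approx(2.0)
        assert cov == pytest.approx(4.0)
        assert cv == pytest.approx(100.0)


class TestAxisCorrelations:
    def test_linear_dependence_and_constant_axis(self):
        x = np.linspace(0, 1, 50)
        # 0.25 is exactly representable, so the axis is exactly constant
        samples = np.column_stack([x, 2 * x + 1, np.full(50, 0.25)])
        cxy, cyz, cxz = axis_correlations(samples)
        assert cxy == pytest.approx(1.0)
        assert cyz == 0.0 and cxz == 0.0

    def test_anticorrelated(self):
        x = np.linspace(0, 1, 50)
        samples = np.column_stack([x, -x, x**2])
        assert axis_correlations(samples)[0] == pytest.approx(-1.0)

    def test_independent_noise_axes_nearly_uncorrelated(self, rng):
        samples = rng.normal(size=(1600, 3))
        assert all(abs(c) < 0.1 for c in axis_correlations(samples))


class TestExtractFeatures:
    def test_all_15_features_finite(self, rng):
        w = make_window(rng.normal(0.5, 0.2, size=(160, 3)))
        fw = extract_features(w)
        assert fw.values().shape == (15,)
        assert np.all(np.isfinite(fw.values()))

    def test_shaker_tone_window(self):
        w = tone_window(2.0, rate=10.0, seconds=16, amp=0.5, offset=2.0)
        fw = extract_features(w)
        assert fw.df == pytest.approx(2.0)
        assert fw.p625 >= 0.99

    def test_scaling_homogeneity(self, rng):
        samples = rng.normal(0.4, 0.3, size=(160, 3)) + [1.0, 0.1, 0.1]
        a = extract_features(make_window(samples))
        b = extract_features(make_window(2.0 * samples))
        assert b.mvm == pytest.approx(2 * a.mvm, rel=1e-9)
        assert b.sdvm == pytest.approx(2 * a.sdvm, rel=1e-9)
        assert b.covariance == pytest.approx(4 * a.covariance, rel=1e-9)
        for inv in ("cv", "corr_xy", "corr_yz", "corr_xz", "df", "p625", "entropy",
                    "mean_angle", "sd_angle", "fpdf"):
            assert getattr(b, inv) == pytest.approx(getattr(a, inv), rel=1e-9, abs=1e-12)

    def test_deterministic(self, rng):
        samples = rng.normal(size=(64, 3))
        a = extract_features(make_window(samples))
        b = extract_features(make_window(samples.copy()))
        np.testing.assert_array_equal(a.values(), b.values())

    @pytest.mark.parametrize("n", [16, 33, 100, 256])
    def test_matches_brute_force_oracle(self, n, rng):
        """Every feature agrees with direct-summation/termwise formulas."""
        samples = rng.normal(0.3, 0.4, size=(n, 3)) + [0.8, 0.2, 0.1]
        fw = extract_features(make_window(samples, rate=10.0))
        expected = naive_features(samples, 10.0)
        for name in FEATURE_NAMES:
            assert getattr(fw, name) == pytest.approx(
                expected[name], rel=1e-6, abs=1e-9
            ), name

    def test_batch_path_matches_scalar_path(self, rng):
        rec = AccelRecording("d", 10.0, rng.normal(0.5, 0.3, size=(480, 3)))
        spec = WindowSpec(4.0)
        table = featurize(rec, spec)
        for w in segment_windows(rec, spec):
            fw = extract_features(w)
            row = table.iloc[w.window_index]
            for name in FEATURE_NAMES:
                assert row[name] == pytest.approx(getattr(fw, name), rel=1e-9, abs=1e-12)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_band_fraction_complement(self, seed):
        r = np.random.default_rng(seed)
        vm = r.normal(1.0, 0.3, size=80)
        freqs, mod = vm_spectrum(vm, 10.0)
        inside = power_fraction_band(freqs, mod, 0.6, 2.5)
        below = power_fraction_band(freqs, mod, -1.0, 0.6 - 1e-9)
        above = power_fraction_band(freqs, mod, 2.5 + 1e-9, 100.0)
        assert inside + below + above == pytest.approx(1.0, abs=1e-9)
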
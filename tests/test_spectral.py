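"""Spectral decomposition: oracle equivalence, reconstruction, features."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oscspec as osc
from oscspec.errors import ConfigError, DegenerateInputError, SamplingGridError
from oscspec.spectral import Spectrum
from oscspec.synthetic import class_preset, generate_profile


def dft_oracle(ts: osc.TimeSeries) -> np.ndarray:
    """Brute-force O(n^2) direct summation with the amplitude convention
    (independent of the FFT path): returns [c0, (c_p, d_p) for p=1..P]."""
    v = ts.values
    n = ts.n
    t = ts.times - ts.times[0]
    w = 2 * np.pi / (n * ts.dt)
    P = n // 2
    c = np.zeros(P + 1)
    d = np.zeros(P + 1)
    c[0] = sum(v) / n
    for p in range(1, P + 1):
        cp = sum(v[k] * np.sin(p * w * t[k]) for k in range(n)) * 2 / n
        dp = sum(v[k] * np.cos(p * w * t[k]) for k in range(n)) * 2 / n
        if n % 2 == 0 and p == P:
            cp, dp = 0.0, dp / 2
        c[p], d[p] = cp, dp
    return c, d


@pytest.mark.parametrize("n", [5, 8, 13, 48, 64])
def test_spectrum_matches_bruteforce_oracle(n, rng):
    """FFT-path coefficients equal direct trigonometric summation."""
    ts = osc.TimeSeries(np.arange(n) * 0.5, rng.normal(size=n))
    spec = osc.compute_spectrum(ts)
    c, d = dft_oracle(ts)
    np.testing.assert_allclose(spec.offset, c[0], atol=1e-9)
    np.testing.assert_allclose(spec.sin_coeffs, c[1:], atol=1e-9)
    np.testing.assert_allclose(spec.cos_coeffs, d[1:], atol=1e-9)


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("n", [6, 7, 48])
def test_reconstruction_roundtrip(n, seed):
    """Trigonometric reconstruction reproduces any input series."""
    r = np.random.default_rng(seed)
    ts = osc.TimeSeries(np.arange(n) * 1.0, r.normal(size=n) * 5)
    spec = osc.compute_spectrum(ts)
    np.testing.assert_allclose(osc.reconstruct(spec), ts.values, atol=1e-9)


def test_parseval_identity(rng):
    """Sum of squared values equals the quadratic form of coefficients."""
    n = 48
    ts = osc.TimeSeries(np.arange(n) * 1.0, rng.normal(size=n))
    s = osc.compute_spectrum(ts)
    quad = s.offset**2 + 0.5 * np.sum(s.sin_coeffs[:-1] ** 2 + s.cos_coeffs[:-1] ** 2)
    quad += s.cos_coeffs[-1] ** 2  # Nyquist stores the full amplitude at 1/n
    np.testing.assert_allclose(np.mean(ts.values**2), quad, rtol=1e-9)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    a=st.floats(-5, 5, allow_nan=False),
    b=st.floats(-5, 5, allow_nan=False),
    seed=st.integers(0, 1000),
)
def test_linearity(a, b, seed):
    """Coefficients of a*x + b*y are a*coeffs(x) + b*coeffs(y)."""
    r = np.random.default_rng(seed)
    t = np.arange(24) * 1.0
    x, y = r.normal(size=24), r.normal(size=24)
    sx = osc.compute_spectrum(osc.TimeSeries(t, x))
    sy = osc.compute_spectrum(osc.TimeSeries(t, y))
    sz = osc.compute_spectrum(osc.TimeSeries(t, a * x + b * y))
    np.testing.assert_allclose(
        sz.sin_coeffs, a * sx.sin_coeffs + b * sy.sin_coeffs, atol=1e-9
    )
    np.testing.assert_allclose(
        sz.cos_coeffs, a * sx.cos_coeffs + b * sy.cos_coeffs, atol=1e-9
    )


def test_constant_series_has_offset_only():
    ts = osc.TimeSeries(np.arange(12) * 2.0, np.full(12, 5.0))
    spec = osc.compute_spectrum(ts)
    assert spec.magnitudes[0] == pytest.approx(5.0, abs=1e-12)
    assert np.all(spec.magnitudes[1:] < 1e-9)


def test_pure_harmonic_identity():
    """cos(2*w0*t) on 48 hourly points -> H(2) = 1, all else ~0."""
    t = np.arange(48.0)
    w0 = 2 * np.pi / 48
    spec = osc.compute_spectrum(osc.TimeSeries(t, np.cos(2 * w0 * t)))
    assert spec.magnitudes[2] == pytest.approx(1.0, abs=1e-12)
    others = np.delete(spec.magnitudes, 2)
    assert np.all(np.abs(others) < 1e-9)


def test_clean_circadian_profile_peaks_only_at_spec_indices():
    """A noiseless clean-oscillator profile has nonzero H exactly at
    its constructed indices {0, 2, 4}."""
    spec = dataclasses.replace(class_preset("nr1d2_like"), noise_sd=0.0)
    ts = generate_profile(spec, seed=0)
    mags = osc.compute_spectrum(ts).magnitudes
    assert np.all(mags[[0, 2, 4]] > 0.1)
    assert np.all(np.delete(mags, [0, 2, 4]) < 1e-9)


def test_linear_trend_leaks_into_low_indices():
    """A pure linear trend produces magnitude above the noise floor at
    several indices including p = 1."""
    t = np.arange(48.0)
    spec = osc.compute_spectrum(osc.TimeSeries(t, 0.05 * t))
    assert spec.magnitudes[1] > 3 * osc.noise_floor(spec)
    assert np.count_nonzero(spec.magnitudes[1:] > 1e-9) > 3


class TestMovingAverage:
    def test_constant_unchanged(self):
        ts = osc.TimeSeries(np.arange(6) * 1.0, np.full(6, 2.5))
        np.testing.assert_allclose(osc.moving_average(ts).values, 2.5)

    def test_four_point_example(self):
        ts = osc.TimeSeries(np.arange(4) * 1.0, [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(
            osc.moving_average(ts, 3.0).values, [1.5, 2.0, 3.0, 3.5]
        )

    def test_attenuates_nyquist(self):
        ts = osc.TimeSeries(np.arange(10) * 1.0, [1.0, -1.0] * 5)
        out = osc.moving_average(ts, 3.0)
        assert np.all(np.abs(out.values) < 1.0)

    def test_window_below_sampling_interval_rejected(self):
        ts = osc.TimeSeries(np.arange(6) * 2.0, np.arange(6.0))
        with pytest.raises(ConfigError):
            osc.moving_average(ts, 1.0)


class TestNoiseFloor:
    def test_noiseless_harmonic_floor_is_zero(self):
        t = np.arange(48.0)
        spec = osc.compute_spectrum(osc.TimeSeries(t, np.cos(2 * np.pi * t / 24)))
        assert osc.noise_floor(spec) == pytest.approx(0.0, abs=1e-12)

    def test_constant_upper_half(self):
        P = 12
        c = np.zeros(P)
        d = np.zeros(P)
        d[P // 2 :] = 0.2  # indices p = 7..12, the whole upper half
        spec = Spectrum(2 * np.pi / 24, c, d, offset=1.0, n_points=24, dt=1.0)
        assert osc.noise_floor(spec) == pytest.approx(0.2)

    def test_too_few_components_rejected(self):
        t = np.arange(8.0)
        spec = osc.compute_spectrum(osc.TimeSeries(t, np.sin(t)))
        with pytest.raises(DegenerateInputError):
            osc.noise_floor(spec)

    def test_white_noise_floor_matches_analytic_scale(self):
        """Monte-Carlo mean of the floor lies within a factor 3 of the
        analytic median of the per-index magnitude distribution
        (Rayleigh, scale sigma*sqrt(2/n))."""
        n, sigma = 48, 0.7
        r = np.random.default_rng(2)
        t = np.arange(n) * 1.0
        floors = [
            osc.noise_floor(osc.compute_spectrum(osc.TimeSeries(t, r.normal(0, sigma, n))))
            for _ in range(10_000)
        ]
        analytic = sigma * np.sqrt(2 / n) * np.sqrt(np.log(4))
        ratio = np.mean(floors) / analytic
        assert 1 / 3 < ratio < 3


class TestDetectFundamental:
    def test_pure_harmonic_with_small_noise(self):
        t = np.arange(48.0)
        r = np.random.default_rng(3)
        v = np.cos(2 * np.pi * t / 24) + r.normal(0, 0.02, 48)
        assert osc.detect_fundamental(osc.compute_spectrum(osc.TimeSeries(t, v))) == 2

    def test_trend_free_mixed_harmonic_profile(self):
        """A 16-h base-period signal with a stronger 8-h component is
        detected at the base index (p=3), not at the strongest peak."""
        spec = dataclasses.replace(
            class_preset("ttr_like"), noise_sd=0.0, trend_slope=0.0
        )
        ts = generate_profile(spec, seed=0)
        s = osc.compute_spectrum(ts)
        assert osc.detect_fundamental(s) == 3
        assert int(np.argmax(s.magnitudes[1:]) + 1) == 6

    def test_all_noise_mostly_none_found(self):
        """False-detection rate on pure noise, against the Monte-Carlo
        oracle rate (~0.8 for the 12-sample upper-half median floor)."""
        r = np.random.default_rng(123)
        t = np.arange(48.0)
        none = sum(
            osc.detect_fundamental(osc.compute_spectrum(osc.TimeSeries(t, r.normal(0, 1, 48)))) is None
            for _ in range(1000)
        )
        assert none / 1000 >= 0.75


class TestExtractFeatures:
    def test_readoff_by_construction(self):
        t = np.arange(48.0)
        w0 = 2 * np.pi / 48
        v = 3 + 2 * np.cos(2 * w0 * t) + 0.5 * np.cos(4 * w0 * t)
        f = osc.extract_features(osc.compute_spectrum(osc.TimeSeries(t, v)), 2)
        assert f.period == pytest.approx(24.0)
        assert f.offset_strength == pytest.approx(3.0)
        assert f.amplitude == pytest.approx(2.0)
        assert f.harmonic1 == pytest.approx(0.5)
        assert f.harmonic2 == pytest.approx(0.0, abs=1e-9)
        assert f.harmonic3 == pytest.approx(0.0, abs=1e-9)

    def test_double_peak_profile_harmonic_exceeds_fundamental(self):
        spec = dataclasses.replace(class_preset("pde12_like"), noise_sd=0.0)
        ts = generate_profile(spec, seed=0)
        f = osc.extract_features(osc.compute_spectrum(ts), 2)
        assert f.harmonic1 > f.amplitude

    def test_detected_fundamental_on_pure_sinusoid(self):
        t = np.arange(48.0)
        v = 1.7 * np.cos(2 * np.pi * t / 16 - 0.3)
        s = osc.compute_spectrum(osc.TimeSeries(t, v))
        fund = osc.detect_fundamental(s)
        f = osc.extract_features(s, fund)
        assert f.amplitude == pytest.approx(1.7, rel=1e-9)
        assert f.harmonic1 == pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_harmonics_rejected(self):
        t = np.arange(48.0)
        s = osc.compute_spectrum(osc.TimeSeries(t, np.sin(t)))
        with pytest.raises(ConfigError):
            osc.extract_features(s, 7)  # 4*7 > 24


class TestGridValidation:
    def test_nonuniform_rejected(self):
        with pytest.raises(SamplingGridError):
            osc.TimeSeries([0.0, 1.0, 2.5, 3.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_short_rejected(self):
        with pytest.raises(SamplingGridError):
            osc.TimeSeries([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_decreasing_rejected(self):
        with pytest.raises(SamplingGridError):
            osc.TimeSeries([0.0, 2.0, 1.0, 3.0], np.ones(4))
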
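"""Fourier spectra of sampled oscillating signals.

A signal sampled at *n* uniform points over a record of span ``n * dt``
hours is decomposed as

    H(t) = c0 + sum_{p>=1} c_p sin(p w t) + d_p cos(p w t),

with base frequency ``w = 2*pi / (n*dt)`` radians/hour and phases
measured from the first sample.  The magnitude spectrum is H(0) = c0 and
H(p) = sqrt(c_p**2 + d_p**2).

Coefficients use the *amplitude* convention: ``c_p = (2/n) * sum v_k
sin(p w t_k)`` and likewise for ``d_p``, so a pure unit-amplitude
harmonic contributes H(p) = 1 at its index.  For even *n* the Nyquist
component p = n/2 is the single exception: its cosine coefficient uses a
factor 1/n (the sampled Nyquist cosine is not attenuated by aliasing, and
this choice makes the trigonometric reconstruction exact) and its sine
coefficient is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .timeseries import TimeSeries

__all__ = [
    "Spectrum",
    "FeatureVector",
    "compute_spectrum",
    "reconstruct",
    "moving_average",
    "noise_floor",
    "extract_features",
    "detect_fundamental",
    "write_spectrum",
]


@dataclass(frozen=True)
class Spectrum:
    """Fourier coefficients and magnitudes of a uniformly sampled signal.

    Attributes
    ----------
    base_frequency
        w = 2*pi / record span, radians/hour; harmonic p sits at p*w.
    sin_coeffs, cos_coeffs
        c_p and d_p for p = 1..P with P = floor(n/2).
    offset
        c0, the signal mean.
    magnitudes
        H(p) for p = 0..P; H(0) = c0 (signed), H(p>=1) >= 0.
    n_points, dt
        Size and spacing of the originating grid (needed to reconstruct).
    """

    base_frequency: float
    sin_coeffs: np.ndarray
    cos_coeffs: np.ndarray
    offset: float
    n_points: int
    dt: float

    @property
    def magnitudes(self) -> np.ndarray:
        mags = np.empty(self.sin_coeffs.size + 1)
        mags[0] = self.offset
        mags[1:] = np.hypot(self.sin_coeffs, self.cos_coeffs)
        return mags

    @property
    def max_index(self) -> int:
        """P = floor(n/2), the largest resolvable harmonic index."""
        return int(self.sin_coeffs.size)


def compute_spectrum(ts: TimeSeries) -> Spectrum:
    """Decompose a uniformly sampled series into harmonic coefficients.

    The grid requirements (uniform spacing, length >= 4) are enforced by
    :class:`~oscspec.timeseries.TimeSeries` itself.
    """
    v = ts.values
    n = ts.n
    P = n // 2
    F = np.fft.rfft(v)
    c0 = float(F[0].real / n)
    d = (2.0 / n) * F.real[1 : P + 1]
    c = (-2.0 / n) * F.imag[1 : P + 1]
    if n % 2 == 0:
        # Nyquist convention: factor 1/n, pure cosine (see module docstring)
        d[-1] = F.real[P] / n
        c[-1] = 0.0
    omega = 2.0 * np.pi / ts.span
    return Spectrum(omega, c, d, c0, n, ts.dt)


def reconstruct(spec: Spectrum, times: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the trigonometric sum at ``times`` (relative to the record
    start; default the original grid).  On the original grid this
    reproduces the input values to machine precision."""
    if times is None:
        times = np.arange(spec.n_points) * spec.dt
    t = np.asarray(times, dtype=float)
    p = np.arange(1, spec.max_index + 1)
    phase = np.outer(t, p) * spec.base_frequency
    return (
        spec.offset
        + np.sin(phase) @ spec.sin_coeffs
        + np.cos(phase) @ spec.cos_coeffs
    )


def moving_average(ts: TimeSeries, window_hours: float = 3.0) -> TimeSeries:
    """Simple (unweighted) centered moving average on the original grid.

    Each output value averages all samples within ``window_hours/2`` of
    the point; edge windows shrink to the available samples so the output
    grid equals the input grid.
    """
    dt = ts.dt
    if window_hours < dt * (1 - 1e-12):
        raise ConfigError(
            f"window ({window_hours} h) must be at least the sampling interval ({dt} h)"
        )
    half = int(np.floor(window_hours / 2.0 / dt + 1e-12))
    kernel = np.ones(2 * half + 1)
    sums = np.convolve(ts.values, kernel, mode="same")
    counts = np.convolve(np.ones(ts.n), kernel, mode="same")
    return ts.with_values(sums / counts)


def noise_floor(spec: Spectrum) -> float:
    """Noise level of a spectrum: median of H(p) over the upper half of
    harmonic indices (p > P/2), where genuine harmonic content of a
    band-limited oscillation is absent."""
    P = spec.max_index
    if P < 8:
        raise DegenerateInputError(f"need P >= 8 spectral components, got {P}")
    mags = spec.magnitudes
    lo = P // 2 + 1
    return float(np.median(mags[lo:]))


@dataclass(frozen=True)
class FeatureVector:
    """The six signal features used for model comparison: base period
    (hours), offset strength H(0), fundamental amplitude, and the first
    three harmonics above the fundamental."""

    period: float
    offset_strength: float
    amplitude: float
    harmonic1: float
    harmonic2: float
    harmonic3: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.period,
                self.offset_strength,
                self.amplitude,
                self.harmonic1,
                self.harmonic2,
                self.harmonic3,
            ]
        )


def extract_features(spec: Spectrum, fundamental_index: int) -> FeatureVector:
    """Read the six features off a spectrum given its fundamental index.

    Harmonic k (k = 1..3) is H((k+1) * fundamental_index); all four
    indices must be resolvable, i.e. ``4 * fundamental_index <= P``.
    """
    f = int(fundamental_index)
    if f < 1:
        raise ConfigError("fundamental_index must be >= 1")
    if 4 * f > spec.max_index:
        raise ConfigError(
            f"harmonics out of range: 4*{f} > P = {spec.max_index}"
        )
    mags = spec.magnitudes
    return FeatureVector(
        period=2.0 * np.pi / (f * spec.base_frequency),
        offset_strength=float(mags[0]),
        amplitude=float(mags[f]),
        harmonic1=float(mags[2 * f]),
        harmonic2=float(mags[3 * f]),
        harmonic3=float(mags[4 * f]),
    )


def detect_fundamental(spec: Spectrum, threshold_mult: float = 3.0) -> int | None:
    """Smallest index p >= 1 whose magnitude exceeds ``threshold_mult``
    times the noise floor; ``None`` when no component clears it.

    No trend removal is attempted here: a linear trend leaks into low
    indices (including p = 1) and its handling is the caller's choice.
    """
    floor = noise_floor(spec)
    mags = spec.magnitudes
    # scale-relative guard so float round-off in a noiseless spectrum
    # (where the floor itself is ~1e-16) is never called a component
    guard = 1e-9 * np.max(np.abs(mags))
    above = np.nonzero(mags[1:] > threshold_mult * floor + guard)[0]
    if above.size == 0:
        return None
    return int(above[0] + 1)


def write_spectrum(path, spec: Spectrum) -> None:
    """Write a spectrum as TSV with columns p, c_p, d_p, H_p."""
    import pandas as pd

    P = spec.max_index
    df = pd.DataFrame(
        {
            "p": np.arange(P + 1),
            "c_p": np.concatenate(([0.0], spec.sin_coeffs)),
            "d_p": np.concatenate(([spec.offset], spec.cos_coeffs)),
            "H_p": spec.magnitudes,
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
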
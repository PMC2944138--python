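"""Synthetic micro-array-like expression time series.

Generates uniformly sampled signals with controlled harmonic content,
linear trend, and additive Gaussian noise, emulating a circadian
time-course design of 48 points at one-hour intervals spanning two
complete periods.  Four named presets reproduce the qualitative spectral
classes seen in such data:

``nr1d2_like``
    clean circadian oscillator: offset plus a dominant fundamental at
    p = 2 and a weaker first harmonic at p = 4.
``pde12_like``
    double-peak class: the component at p = 4 is *stronger* than the
    fundamental at p = 2, so the waveform shows four maxima per record.
``eif2ak3_like``
    downward linear trend plus oscillatory components at p = 4 and a
    dominant p = 6 (base periods 12 h and 8 h — not integer multiples
    of each other once the p = 6 peak is read as a separate component).
``ttr_like``
    upward linear trend plus components at p = 3 (16 h base period) and
    a dominant p = 6.

Preset amplitudes are package constants chosen to realise those
orderings; they are not measurements.  The noise model is i.i.d.
Gaussian on the values — a minimal stand-in for micro-array noise, and
a parameter rather than a commitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .timeseries import TimeSeries, read_series, write_series

__all__ = [
    "ProfileSpec",
    "DatasetSpec",
    "generate_profile",
    "class_preset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for one synthetic expression profile.

    ``harmonics`` is a list of (index p, amplitude, phase radians)
    triples; the signal is

        offset + trend_slope*t + sum A*cos(p*w0*t - phase) + noise,

    with w0 = 2*pi/(n_points*dt) and noise ~ N(0, noise_sd**2) i.i.d.
    """

    label: str
    offset: float = 0.0
    harmonics: tuple[tuple[int, float, float], ...] = ()
    trend_slope: float = 0.0
    noise_sd: float = 0.0
    n_points: int = 48
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ConfigError("n_points must be >= 8")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        harm = tuple((int(p), float(a), float(ph)) for p, a, ph in self.harmonics)
        for p, a, _ in harm:
            if p < 1 or a < 0:
                raise ConfigError("harmonic indices must be >= 1 and amplitudes >= 0")
        object.__setattr__(self, "harmonics", harm)


@dataclass(frozen=True)
class DatasetSpec:
    """A collection of profiles sharing one global seed; labels unique."""

    profiles: tuple[ProfileSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ConfigError("profile labels must be unique")


def generate_profile(spec: ProfileSpec, seed: int) -> TimeSeries:
    """Generate one profile; bit-reproducible for a given seed."""
    t = np.arange(spec.n_points) * spec.dt
    w0 = 2.0 * np.pi / (spec.n_points * spec.dt)
    v = spec.offset + spec.trend_slope * t
    for p, amp, phase in spec.harmonics:
        v = v + amp * np.cos(p * w0 * t - phase)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    return TimeSeries(t, v, label=spec.label)


#: preset constants: qualitative spectral classes (see module docstring)
_PRESETS: dict[str, ProfileSpec] = {
    "nr1d2_like": ProfileSpec(
        label="1416958_at",
        offset=3.0,
        harmonics=((2, 1.0, 0.6), (4, 0.35, 1.1)),
        noise_sd=0.08,
    ),
    "pde12_like": ProfileSpec(
        label="1454963_at",
        offset=2.4,
        harmonics=((2, 0.45, 0.2), (4, 0.8, 1.5)),
        noise_sd=0.08,
    ),
    "eif2ak3_like": ProfileSpec(
        label="1449278_at",
        offset=3.2,
        trend_slope=-0.02,
        harmonics=((4, 0.25, 0.9), (6, 0.5, 2.0)),
        noise_sd=0.06,
    ),
    "ttr_like": ProfileSpec(
        label="1455913_x_at",
        offset=3.0,
        trend_slope=0.02,
        harmonics=((3, 0.3, 0.4), (6, 0.55, 1.3)),
        noise_sd=0.06,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def class_preset(name: str) -> ProfileSpec:
    """Return the ProfileSpec for one of the four named signal classes.

    Use :func:`dataclasses.replace` to switch off noise or the trend
    when a clean signature is wanted (e.g. ``replace(spec,
    noise_sd=0.0, trend_slope=0.0)``).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {', '.join(_PRESETS)}"
        ) from None


def generate_dataset(ds: DatasetSpec) -> dict[str, TimeSeries]:
    """Generate all profiles of a dataset; per-profile seeds are derived
    from the global seed deterministically."""
    seeds = np.random.SeedSequence(ds.seed).generate_state(len(ds.profiles))
    return {
        p.label: generate_profile(p, int(s) & 0x7FFFFFFF)
        for p, s in zip(ds.profiles, seeds)
    }


def write_dataset(ds: DatasetSpec, path) -> dict[str, TimeSeries]:
    """Generate and write a dataset as one TSV; returns the series."""
    series = generate_dataset(ds)
    grids = {ts.n for ts in series.values()} | {ts.dt for ts in series.values()}
    if len({ts.n for ts in series.values()}) > 1:
        raise ConfigError("all profiles in one file must share n_points and dt")
    write_series(path, series)
    return series


def read_dataset(path) -> dict[str, TimeSeries]:
    """Read a dataset file back into labelled series (round-trip exact
    to the written decimal precision)."""
    return read_series(path)
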
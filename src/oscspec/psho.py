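"""Positive Simple Harmonic Oscillator (PSHO): closed-form solutions,
feature-based fitting, and gene-knockout / copy-number mutant predictions.

The model couples two non-negative concentrations S and R:

    dS/dt = -C_S + alpha**2 * R(t)
    dR/dt = +C_R - beta**2  * S(t)

with closed-form solutions

    S(t) = C_R/beta**2  + A1*cos(w t) + A2*sin(w t)
    R(t) = C_S/alpha**2 + (beta/alpha) * (A2*cos(w t) - A1*sin(w t))

and angular frequency ``w = alpha*beta``.  Setting C_S = C_R = 0 recovers
the plain simple harmonic oscillator.  Both substances oscillate at the
same single frequency with R leading S by a quarter period; those two
structural facts are the model's invalidation levers — data with unequal
frequencies, a different phase offset, or harmonic content above noise
reject the model outright.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DegenerateInputError, ModelInconsistencyError
from .spectral import compute_spectrum, detect_fundamental
from .timeseries import TimeSeries

__all__ = [
    "PSHOParams",
    "PSHOFeatures",
    "PositivityWarning",
    "psho_solution",
    "measure_psho_features",
    "fit_psho_from_features",
    "PSHOFit",
    "KnockoutReport",
    "psho_knockout_prediction",
    "CopyNumberReport",
    "psho_copy_number_prediction",
]

#: model-fixed phase difference phase(R) - phase(S), radians (R leads S)
MODEL_PHASE_DIFF = -math.pi / 2


class PositivityWarning(UserWarning):
    """Parameter set admits negative concentrations at some times."""


@dataclass(frozen=True)
class PSHOParams:
    """Parameters of the PSHO: rate constants alpha, beta (>0), constant
    removal/production rates C_S, C_R (>=0), and integration constants
    A1, A2 fixed by initial conditions."""

    alpha: float
    beta: float
    C_S: float
    C_R: float
    A1: float
    A2: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError("alpha and beta must be positive")
        if self.C_S < 0 or self.C_R < 0:
            raise ConfigError("C_S and C_R must be non-negative")

    @property
    def omega(self) -> float:
        """Angular frequency of oscillation, radians/hour."""
        return self.alpha * self.beta

    @property
    def offset_S(self) -> float:
        """Long-term average of S: depends only on R's rates."""
        return self.C_R / self.beta**2

    @property
    def offset_R(self) -> float:
        """Long-term average of R: depends only on S's rates."""
        return self.C_S / self.alpha**2

    @property
    def osc_amplitude(self) -> float:
        return math.hypot(self.A1, self.A2)

    def positivity_satisfied(self) -> bool:
        """Whether S(t) >= 0 and R(t) >= 0 for all t.  Violation is a
        warning state, not an error: the plain-SHO limit (C_S = C_R = 0)
        and exploratory parameter sets remain representable."""
        a = self.osc_amplitude
        return self.offset_S >= a - 1e-15 and self.offset_R >= (self.beta / self.alpha) * a - 1e-15


@dataclass(frozen=True)
class PSHOFeatures:
    """The seven measurable quantities of a pair of oscillating signals:
    two amplitudes, two frequencies (radians/hour), two offsets, and the
    phase difference phase(R) - phase(S) (radians; ``None`` if phase
    information is lacking)."""

    amp_S: float
    amp_R: float
    freq_S: float
    freq_R: float
    offset_S: float
    offset_R: float
    phase_diff: float | None = None


def psho_solution(params: PSHOParams, times: np.ndarray) -> tuple[TimeSeries, TimeSeries]:
    """Evaluate the closed-form S(t) and R(t) on a uniform grid."""
    if not params.positivity_satisfied():
        warnings.warn(
            "parameter set admits negative concentrations (positivity "
            "condition violated); solutions are still exact",
            PositivityWarning,
            stacklevel=2,
        )
    t = np.asarray(times, dtype=float)
    w = params.omega
    c, s = np.cos(w * t), np.sin(w * t)
    S = params.offset_S + params.A1 * c + params.A2 * s
    R = params.offset_R + (params.beta / params.alpha) * (params.A2 * c - params.A1 * s)
    return TimeSeries(t, S, label="S"), TimeSeries(t, R, label="R")


def _phase_at_index(spec, p: int) -> float:
    """Phase phi of A*cos(p*w*t - phi) from the stored coefficients."""
    return math.atan2(spec.sin_coeffs[p - 1], spec.cos_coeffs[p - 1])


def measure_psho_features(S: TimeSeries, R: TimeSeries) -> PSHOFeatures:
    """Measure the seven fit quantities from a pair of sampled signals
    via their spectra.  The record should span whole periods."""
    spec_S, spec_R = compute_spectrum(S), compute_spectrum(R)
    f_S = detect_fundamental(spec_S)
    f_R = detect_fundamental(spec_R)
    if f_S is None or f_R is None:
        raise DegenerateInputError("no oscillatory component detected in S or R")
    dphi = _phase_at_index(spec_R, f_R) - _phase_at_index(spec_S, f_S)
    dphi = (dphi + math.pi) % (2 * math.pi) - math.pi
    return PSHOFeatures(
        amp_S=float(spec_S.magnitudes[f_S]),
        amp_R=float(spec_R.magnitudes[f_R]),
        freq_S=f_S * spec_S.base_frequency,
        freq_R=f_R * spec_R.base_frequency,
        offset_S=spec_S.offset,
        offset_R=spec_R.offset,
        phase_diff=dphi,
    )


@dataclass(frozen=True)
class PSHOFit:
    """Result of fitting: recovered parameters plus an ambiguity flag set
    when missing phase information leaves the S/R role assignment
    two-fold ambiguous."""

    params: PSHOParams
    ambiguous: bool
    roles_swapped: bool = False


def fit_psho_from_features(feat: PSHOFeatures, freq_tol: float = 0.05) -> PSHOFit:
    """Invert the closed form: six measured quantities fix the six
    constants.

    The model demands equal frequencies for S and R; a mismatch beyond
    ``freq_tol`` (relative) raises :class:`ModelInconsistencyError` —
    that exception *is* the invalidation verdict, not a numerical
    failure.  The absolute phase of S is not identifiable (the time
    origin is free), so the fit places the phase origin at S's cosine
    peak: A1 = amp_S, A2 = 0.  A supplied ``phase_diff`` is checked
    against the model's fixed value of -pi/2 (R leads S by a quarter
    period); a value near +pi/2 means the two signals' roles are swapped
    and the fit swaps them; any other value is inconsistent with the
    model.  Without phase information the two-fold role ambiguity is
    flagged.
    """
    if feat.amp_R <= 0 or feat.amp_S <= 0:
        raise DegenerateInputError("amplitudes must be positive to fit the PSHO")
    if feat.freq_S <= 0 or feat.freq_R <= 0:
        raise DegenerateInputError("frequencies must be positive")
    if abs(feat.freq_S - feat.freq_R) > freq_tol * feat.freq_S:
        raise ModelInconsistencyError(
            f"S and R frequencies differ by more than {freq_tol:.0%} "
            f"({feat.freq_S:.4g} vs {feat.freq_R:.4g} rad/h): the PSHO "
            "predicts equal frequencies — model invalidated"
        )

    swapped = False
    f = feat
    if f.phase_diff is not None:
        d = (f.phase_diff + math.pi) % (2 * math.pi) - math.pi
        if abs(d - MODEL_PHASE_DIFF) < 0.35:
            pass
        elif abs(d + MODEL_PHASE_DIFF) < 0.35:
            # roles swapped: the signal labelled S is the model's R
            swapped = True
            f = PSHOFeatures(
                amp_S=f.amp_R, amp_R=f.amp_S,
                freq_S=f.freq_R, freq_R=f.freq_S,
                offset_S=f.offset_R, offset_R=f.offset_S,
                phase_diff=MODEL_PHASE_DIFF,
            )
        else:
            raise ModelInconsistencyError(
                f"phase difference {d:.3f} rad is neither -pi/2 nor +pi/2: "
                "inconsistent with the PSHO's fixed quarter-period lead"
            )

    w = 0.5 * (f.freq_S + f.freq_R)
    alpha = math.sqrt(w * f.amp_S / f.amp_R)
    beta = w / alpha
    params = PSHOParams(
        alpha=alpha,
        beta=beta,
        C_S=f.offset_R * alpha**2,
        C_R=f.offset_S * beta**2,
        A1=f.amp_S,
        A2=0.0,
    )
    return PSHOFit(params=params, ambiguous=feat.phase_diff is None, roles_swapped=swapped)


@dataclass(frozen=True)
class KnockoutReport:
    """Qualitative prediction for a gene-knockout mutant.  Knockouts
    break the model (solutions stop being positive/bounded), so only the
    direction of change of the partner substance is predicted."""

    knocked_out: str
    affected: str
    breakdown: bool
    direction: str  # "lower" | "higher" | "unchanged"
    reason: str


def psho_knockout_prediction(params: PSHOParams, gene: str) -> KnockoutReport:
    """Predict the partner substance's response to knocking out R or S."""
    if gene == "R":
        # dS/dt = -C_S: linear decay, not positive at all times
        direction = "lower" if params.C_S > 0 else "unchanged"
        return KnockoutReport(
            knocked_out="R",
            affected="S",
            breakdown=True,
            direction=direction,
            reason="with R = 0, dS/dt = -C_S: solution not positive at all times",
        )
    if gene == "S":
        direction = "higher" if params.C_R > 0 else "unchanged"
        return KnockoutReport(
            knocked_out="S",
            affected="R",
            breakdown=True,
            direction=direction,
            reason="with S = 0, dR/dt = +C_R: solution unbounded from above",
        )
    raise ConfigError(f"gene must be 'R' or 'S', got {gene!r}")


@dataclass(frozen=True)
class CopyNumberReport:
    """Exact mutant/wildtype ratios for an N-copy mutant, computed from
    the closed-form solution (never hard-coded)."""

    gene: str
    N: int
    offset_S_ratio: float
    offset_R_ratio: float
    omega_ratio: float
    amp_ratio_ratio: float  # (amp_S/amp_R)_mutant / (amp_S/amp_R)_wildtype


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return float("nan") if num == 0.0 else float("inf")
    return num / den


def psho_copy_number_prediction(
    params: PSHOParams, gene: str, N: int
) -> tuple[PSHOParams, CopyNumberReport]:
    """N-copy mutant of gene R or S.

    Replicating R multiplies its constant production rate C_R by N;
    replicating S multiplies the production-rate parameter alpha**2 by N
    (alpha <- sqrt(N)*alpha).  All other parameters are unchanged.  The
    report's ratios are recomputed from the closed form for both
    parameter sets, so e.g. doubling C_R yields an S-offset ratio of
    exactly 2 while leaving the frequency untouched, and doubling
    alpha**2 halves R's long-term average while scaling the frequency
    and the amplitude ratio amp_S/amp_R by sqrt(2).
    """
    if N < 1:
        raise ConfigError(f"copy number N must be >= 1, got {N}")
    if gene == "R":
        mutant = replace(params, C_R=N * params.C_R)
    elif gene == "S":
        mutant = replace(params, alpha=math.sqrt(N) * params.alpha)
    else:
        raise ConfigError(f"gene must be 'R' or 'S', got {gene!r}")
    wt_amp_ratio = params.alpha / params.beta
    mut_amp_ratio = mutant.alpha / mutant.beta
    report = CopyNumberReport(
        gene=gene,
        N=int(N),
        offset_S_ratio=_ratio(mutant.offset_S, params.offset_S),
        offset_R_ratio=_ratio(mutant.offset_R, params.offset_R),
        omega_ratio=mutant.omega / params.omega,
        amp_ratio_ratio=mut_amp_ratio / wt_amp_ratio,
    )
    return mutant, report
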
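# Methods

## Spectral decomposition

A series of *n* uniform samples over a record of span *n·Δt* hours is
written

    H(t) = c0 + Σ_{p≥1} c_p sin(pωt) + d_p cos(pωt),    ω = 2π/(nΔt),

with phases measured from the first sample.  Coefficients use the
*amplitude* convention, c_p = (2/n)·Σ v_k sin(pωt_k) (likewise d_p), so
a pure unit-amplitude harmonic yields H(p) = √(c_p²+d_p²) = 1 at its
index and H(0) = c0 is the mean.  For even *n* the Nyquist component
p = n/2 uses the factor 1/n with a zero sine part; with that single
convention the finite trigonometric sum reproduces the input exactly,
and Parseval's identity holds in the form mean(v²) = c0² + ½Σ(c²+d²)
+ d²_Nyq.  Computation goes through `numpy.fft.rfft`; the test suite
checks it against a brute-force direct summation.

Derived quantities:

- **noise floor** — median of H(p) over the upper half of indices
  (p > P/2), where band-limited biological oscillations have no genuine
  content.  The median is robust to a residual peak; with only ~P/2
  samples it fluctuates by ~20%, which matters for detection (below).
- **fundamental detection** — smallest p ≥ 1 with H(p) above
  `threshold_mult` (default 3) times the floor, plus a 1e-9-of-max
  guard so float dust in noiseless spectra is never called a component.
  No trend removal is attempted inside detection: a linear trend leaks
  into low indices (including p = 1) and its handling belongs to the
  caller.  On pure white noise this detector false-fires in ~20% of
  records (Monte-Carlo, n = 48): the small-sample floor occasionally
  sits low.  That rate is a property of the estimator, not a bug; raise
  `threshold_mult` when false positives are costly.
- **features** — the six-vector used for model comparison: base period,
  offset H(0), fundamental amplitude H(f), and harmonics H(2f), H(3f),
  H(4f).
- **moving average** — unweighted centered window (default 3 h) on the
  original grid; edge windows shrink to the available samples so the
  grid never shifts.

## The linear oscillator (PSHO)

The closed form (README) makes every prediction analytic.  Fitting
inverts six measured quantities: ω as the mean of the two frequencies
(which must agree within `freq_tol`, default 5% — a mismatch *is* the
invalidation verdict and raises `ModelInconsistencyError`),
α = √(ω·amp_S/amp_R), β = ω/α, C_R = offset_S·β², C_S = offset_R·α².
The absolute phase is not identifiable (free time origin), so A₁ =
amp_S, A₂ = 0; a supplied phase difference is only *checked* against
the model's fixed −π/2 (R leads S by a quarter period) — a value near
+π/2 means the two signals' labels are swapped and the fit swaps them;
anything else is inconsistent with the model.  Without phase
information the two-fold role ambiguity is flagged, not guessed.

Positivity of the solutions (C_R/β² ≥ √(A₁²+A₂²) and the analogous R
condition) is checked and reported as a warning, not a constructor
error: the plain-SHO limit C_S = C_R = 0 and exploratory parameter sets
stay representable.

Copy-number ratios are recomputed from the closed form for wildtype and
mutant rather than hard-coded.  One consequence worth stating: for an
S-replication (α² ← N·α²) the frequency and the amplitude ratio scale
by √N, directly from ω = αβ and amp-ratio = α/β — not by N, as a naive
reading of "α² doubles" might suggest.

## Delay-differential models and their steady cycles

Both nonlinear models are integrated with a fixed-step classical RK4
using the method of steps: delayed values come from 4-point Lagrange
interpolation of the stored trajectory, constant history before t = 0,
and the step is required to resolve the shortest positive delay at
least tenfold so all delayed lookups lie strictly in the past.  Zero
delays degrade to ordinary RK4 stages.  States are clamped at 0 (the
vector field pushes them non-negative anyway; the clamp absorbs
round-off undershoot).  The Heaviside kink of the two-gene coupling is
handled by step smallness, not event location; it reduces the observed
convergence order to ~2, and the accuracy contract is therefore the
step-doubling test (sup-norm change < 1e-4 at dt = 0.025 for the
worked-example two-gene set; < 1e-4 at the default step for the smooth
single-gene model).  A hard per-run budget of 2×10⁶ steps turns
pathological parameter corners into a reproducible `IntegrationError`
instead of an unbounded run.

**Two-gene coupling orientation.**  With the drive written as
max(P_delayed − Q_delayed, 0) the system is, after the substitution
Q → −Q, a cooperative delay system: both feedback loops are positive,
and such systems converge — the structure is a bistable latch that
cannot oscillate for any parameters or history (we verified this
numerically from constant and oscillatory histories and it follows
from monotone-systems theory).  The orientation used here,
X = max(Q(t−δ_Q) − P(t−δ_P), 0), is the unique minimal reorientation
that closes a delayed negative loop; it oscillates robustly at the
standard parameter set and reproduces the equal-period law and the
double-peak-reachability asymmetry.  The integrator was cross-checked
against R's `deSolve::dede` (agreement to 4–5 decimals in the
steady-state envelope of both models).

**Automatic integration settings** (`auto_config`): characteristic time
t_char = max(longest delay, slowest 1/k); burn-in 40·t_char; recorded
stretch 32·t_char; dt = min(shortest positive delay/20, 0.2/k_max,
t_char/50).  For the two-gene model the constant history is asymmetric
(P at its carrying scale V_P/k_P, Q at a tenth of its own): a symmetric
history is a dead fixed point of the thresholded coupling (X ≡ 0, P
decays), so the system must be kicked into the engaged regime.

**Steady-cycle extraction.**  The period is found from the lagged
self-distance D(L) = rms(x[L:] − x[:−L]) normalised by √2·std —
robust for arbitrary repeating waveforms, where successive-peak timing
fails on double-peak shapes whose local maxima alternate at half-period
spacing.  Integer-lag dips are quantisation-limited (a dip falling
between grid lags looks shallow, and deeper dips appear at whichever
period *multiple* best aligns with the grid — a vernier effect), so
candidate dips are compared only after continuous refinement on a cubic
spline of the trajectory.  Subharmonic content below a normalised
mismatch of 5×10⁻³ (the scale of integration artifacts at the default
steps) is treated as negligible when choosing between a period and its
double, in both directions.  A trajectory whose refined mismatch
exceeds 0.5%, or whose trailing cycle-to-cycle amplitude drift exceeds
1%, is rejected as not settled (`NotConvergedError`); one with
peak-to-trough range below 10⁻⁶ of its mean is flat
(`FlatSignalError`).  The trailing `n_periods` (default 2) periods are
then resampled with a cubic spline to 24 points per period — 48 points
per two periods, mirroring the circadian experimental design, so a
model cycle and a measured record share harmonic indices and the
steady-cycle fundamental index equals `n_periods` by construction.

## Synthetic data

The generator is the analyzer's exact inverse on the harmonic model:
values = offset + slope·t + Σ A·cos(pω₀t − φ) + N(0, σ²) i.i.d., on the
48-point hourly grid by default.  Four presets realise the qualitative
signal classes seen in circadian liver data: a clean 24-h oscillator
(peaks at p ∈ {0,2,4}, fundamental dominant), a double-peak class
(H(4) > H(2)), and two trending classes (one downward with components
at p ∈ {4,6}, one upward with p ∈ {3,6}, the p = 6 component dominant
in both).  Preset amplitudes are package constants chosen to realise
those orderings, not measurements.  Gaussian noise is a minimal
stand-in for micro-array noise — the generator emulates harmonic
content, trends and point scatter, not probe-level effects,
normalisation artifacts or heteroscedasticity, so passing tests speak
to the method's behaviour on well-behaved signals, not to any specific
platform's error structure.  Trends are linear; both raw and detrended
analysis paths are exercised because presets carry their trends
explicitly.

## Model selection

**Scans.**  Parameters are drawn independently log-uniformly over
[0.01, 100] per parameter (the Hill exponent uniformly from {2,3,4});
each draw is integrated with automatic settings and reduced to its
steady cycle; failures and non-oscillating draws are counted, never
resampled, so hit rates are per-draw and reproducible by seed.  A draw
counts as oscillating only if its cycle's spectral content is at least
0.1% of its level and its detected fundamental sits at the steady-cycle
index; a *hit* additionally requires the fundamental to carry ≥ 1% of
the dominant peak.  These guards exist because classifications must
survive step-halving: spectral magnitude ratios converge with dt,
whereas lag-domain subharmonic measures near the 5×10⁻³ tolerance can
flip.  The default budget is 2000 draws per model, a desk-scale setting
under which the single-gene model yields zero double-peak hits and the
two-gene model a few — the asymmetry that rejects the single-gene
structure for double-peak signals.

**Matching.**  `match_models` adjusts (n_E, α_E, β_E) with k_E and δ_E
pinned, over a log grid (13×13 per exponent) refined by Nelder–Mead in
log space.  The reported objective is the maximum relative error over
the two leading peaks, but that objective alone is degenerate (two continuous parameters can fit two peak heights
exactly in several places), so candidates within the 10% leading
tolerance are ranked by the subleading (waveform-shape) error plus a
0.01-weighted leading term.  This makes the identity case exact (a
reference generated by the single-gene model is recovered to < 1e-6)
and lands the two-gene match at ~8%/10% leading and ~19% subleading
error.  Exact cross-model matches do not exist: three adjustable
parameters against many independent peaks.

## Copy-number mutants

An N-copy mutant multiplies the mutated gene's maximal production rate
by N (α_E for the single-gene model, V_P for the two-gene model) and
leaves everything else untouched.  Each mutant is re-integrated with
the same settings policy and its six features are divided by the
wildtype's; ratios whose wildtype feature sits below 3× the spectral
noise floor are reported as undefined rather than as inflated
quotients; a mutant that fails to reach a steady cycle is recorded as a
regime change for that N, not an error.  The uncoupled second substance
of the expanded single-gene model is unaffected by construction (all
its ratios are exactly 1) and is not simulated.  Copy numbers default
to 1..5.

## Known limitations

- The double-peak hit rate in the full region is a few per two
  thousand draws; scans at much smaller budgets can legitimately find
  none.  The decade-wide box around the worked-example rates is a
  denser place to look.
- Classification of marginal oscillators (relative amplitude near the
  0.1% gate, subharmonics near the 5×10⁻³ tolerance) is necessarily
  threshold-based; the thresholds were chosen at the scale of the
  integrator's own artifacts and are package constants.
- The noise-floor detector's ~20% false-positive rate on pure noise at
  the default threshold is inherent to a 12-sample median floor.
- Feature ratios and spectra are computed on noiseless model output;
  the synthetic generator quantifies noise robustness for the
  *analyzer*, not for the model-selection pipeline end-to-end.
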
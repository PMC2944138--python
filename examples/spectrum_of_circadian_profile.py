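"""Decompose a synthetic circadian expression profile into its spectrum.

Builds a 48-point, hourly, two-period profile of the clean-oscillator
class (offset + fundamental at p=2 + first harmonic at p=4 + noise),
smooths it with the three-hour moving average, and reads off the
harmonic magnitudes H(p) and the six signal features.
"""

import numpy as np

import oscspec as osc

profile = osc.class_preset("nr1d2_like")
ts = osc.generate_profile(profile, seed=42)
smooth = osc.moving_average(ts, window_hours=3.0)

spec = osc.compute_spectrum(ts)
floor = osc.noise_floor(spec)
fund = osc.detect_fundamental(spec)
feats = osc.extract_features(spec, fund)

print(f"profile {profile.label}: {ts.n} hourly points over {ts.span:g} h")
print(f"noise floor (median of upper-half H(p)): {floor:.4f}")
print(f"fundamental index p = {fund}  ->  base period {feats.period:g} h")
print("H(p) for p = 0..8:", np.round(spec.magnitudes[:9], 3))
print(
    f"features: offset {feats.offset_strength:.3f}, amplitude {feats.amplitude:.3f}, "
    f"harmonics ({feats.harmonic1:.3f}, {feats.harmonic2:.3f}, {feats.harmonic3:.3f})"
)
print(
    "smoothing attenuates high harmonics: H(4) raw "
    f"{spec.magnitudes[4]:.3f} vs smoothed "
    f"{osc.compute_spectrum(smooth).magnitudes[4]:.3f}"
)
# The p=2 peak far above the noise floor is the detection of a 24-hour
# rhythm; the p=4 peak measures how far the waveform departs from a pure
# sinusoid.
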
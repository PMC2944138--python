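"""Signature scan: which model can produce a double-peak spectrum?

Samples each model's parameter region log-uniformly, integrates every
draw to its steady cycle, and tests the spectrum for the double-peak
signature (first harmonic above the fundamental stronger than the
fundamental itself).  A model that never produces an observed signature
anywhere in a generous region is invalidated for that signal class
regardless of its parameter count.

The full analysis samples the whole 0.01-100 region with 2000 draws per
model (see the test suite); double-peak hits are sparse there (a few
per two thousand draws), so this demo scans a decade-wide box around
the worked-example rates, where they are denser, with 300 draws.
"""

import oscspec as osc

single_region = osc.ParameterRegion(
    continuous={
        "alpha_E": (0.1, 10.0), "beta_E": (0.04, 4.0),
        "k_E": (0.04, 4.0), "delta_E": (0.5, 50.0),
    },
    discrete={"n_E": (2, 3, 4)},
)
two_region = osc.ParameterRegion(
    continuous={
        "V_P": (0.15, 15.0), "V_Q": (0.025, 2.5),
        "W_P": (0.02, 2.0), "W_Q": (0.02, 2.0),
        "k_P": (0.04, 4.0), "k_Q": (0.04, 4.0),
        "delta_P": (0.5, 50.0), "delta_Q": (0.5, 50.0),
    }
)

for model, region in (("single_gene", single_region), ("two_gene", two_region)):
    result = osc.scan_model(model, region=region, n=300, seed=0)
    print(
        f"{model:12s}: {result.n_hits:3d} double-peak hits | "
        f"{result.n_oscillating} oscillating, {result.n_non_oscillating} not, "
        f"{result.n_failed} failed of {result.n_sampled} draws"
    )
    for draw, mags in result.hits[:3]:
        pretty = {k: round(v, 3) for k, v in draw.items()}
        print(f"    hit: H(2)={mags[2]:.3g} < H(4)={mags[4]:.3g} at {pretty}")

# The single-gene delayed repressor yields no double-peak spectra: its
# limit cycles always put more weight on the fundamental.  The two-gene
# Heaviside-coupled model reaches the signature in a corner of its
# region, so only it remains viable for double-peak signals.
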
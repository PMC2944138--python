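"""In-silico N-copy mutant comparison of the two delay models.

Each model is first taken at the worked-example (mutually matched)
parameter sets; the mutated gene's maximal production rate is then
scaled by N = 1..5 and every steady-cycle feature is reported as the
ratio mutant/wildtype.  Coarse features respond similarly in both
models; the harmonic responses — especially the second harmonic f5 of E
versus P — diverge and carry the model-discriminating signal.
"""

import oscspec as osc

single = osc.SingleGeneParams(alpha_E=1.0, beta_E=0.4, n_E=3, delta_E=5.0, k_E=0.4)
two = osc.TwoGeneParams(
    V_P=1.5, V_Q=0.25, W_P=0.2, W_Q=0.2, k_P=0.4, k_Q=0.4, delta_P=5.0, delta_Q=5.0
)

repE = osc.mutant_experiment(single, "E")
repP = osc.mutant_experiment(two, "P")

import pandas as pd

table = pd.concat(
    [
        repE.to_frame().assign(model="single_gene"),
        repP.to_frame().assign(model="two_gene"),
    ],
    ignore_index=True,
)
print(table.round(3).to_string(index=False))

for N in (2, 5):
    dE = repE.ratios["E"][N]
    dP = repP.ratios["P"][N]
    print(
        f"N={N}: second-harmonic response E {dE[4]:.2f}x vs P {dP[4]:.2f}x "
        f"(offsets {dE[1]:.2f}x vs {dP[1]:.2f}x)"
    )
# Periods stay near 1x for all substances; offsets and amplitudes rise
# for the mutated E and P and stay flat for the coupled partner Q —
# whose harmonics nevertheless shift, betraying the P-Q interaction that
# the coarse features alone would miss.
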
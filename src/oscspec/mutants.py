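"""In-silico copy-number mutant experiments for the nonlinear models.

An N-copy mutant carries N copies of a gene's coding region, modelled
as an N-fold scaling of that gene's maximal production-rate parameter
with everything else untouched: alpha_E for the single-gene model's E,
V_P for the two-gene model's P.  For each copy number the mutant model
is integrated to its steady cycle and the six spectral features
(period, offset, amplitude, first/second/third harmonics) are compared
to the wildtype as mutant/wildtype ratios — the comparison behind the
copy-number discrimination strategy: coarse features respond similarly
in both models, while the harmonic responses diverge and so carry the
discriminating signal.

The closed-form analogue for the linear oscillator lives in
:mod:`oscspec.psho`; this module handles only the numerically
integrated models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dde import (
    IntegrationConfig,
    SingleGeneParams,
    TwoGeneParams,
    auto_config,
    integrate_single_gene,
    integrate_two_gene,
    steady_cycle,
    steady_cycle_pair,
)
from .errors import ConfigError, FlatSignalError, IntegrationError, NotConvergedError
from .spectral import FeatureVector, compute_spectrum, extract_features, noise_floor

__all__ = ["MutantSpec", "MutantReport", "apply_copy_number", "mutant_experiment"]

FEATURE_NAMES = ("f1_period", "f2_offset", "f3_amplitude", "f4_harm1", "f5_harm2", "f6_harm3")


@dataclass(frozen=True)
class MutantSpec:
    """Which gene to replicate, in which model, at what copy number."""

    model: str  # "single_gene" | "two_gene"
    gene: str   # "E" for single_gene, "P" for two_gene
    N: int

    def __post_init__(self) -> None:
        pairs = {"single_gene": "E", "two_gene": "P"}
        if self.model not in pairs:
            raise ConfigError(f"unknown model {self.model!r}")
        if self.gene != pairs[self.model]:
            raise ConfigError(
                f"gene {self.gene!r} incompatible with model {self.model!r} "
                f"(expected {pairs[self.model]!r})"
            )
        if self.N < 1:
            raise ConfigError("copy number N must be >= 1")


def apply_copy_number(params, spec: MutantSpec):
    """Return the mutant parameter set: alpha_E (single-gene) or V_P
    (two-gene) scaled by N, every other field bit-identical."""
    if spec.model == "single_gene":
        if not isinstance(params, SingleGeneParams):
            raise ConfigError("single_gene mutant needs SingleGeneParams")
        return replace(params, alpha_E=spec.N * params.alpha_E)
    if not isinstance(params, TwoGeneParams):
        raise ConfigError("two_gene mutant needs TwoGeneParams")
    return replace(params, V_P=spec.N * params.V_P)


@dataclass
class MutantReport:
    """Feature ratios mutant/wildtype per substance per copy number.

    ``ratios[substance][N]`` is a length-6 array of the f1..f6 ratios
    (NaN marks features undefined in the wildtype, i.e. below 3x its
    spectral noise floor).  Mutants that fail to oscillate are recorded
    in ``regime_changes`` rather than crashing the experiment.  The
    expanded single-gene model's second, uncoupled substance E' is
    unaffected by construction (all its ratios would be exactly 1) and
    is therefore not simulated.
    """

    model: str
    gene: str
    Ns: tuple[int, ...]
    wildtype: dict[str, FeatureVector]
    ratios: dict[str, dict[int, np.ndarray]]
    regime_changes: list[tuple[int, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for substance, per_n in self.ratios.items():
            for N, r in sorted(per_n.items()):
                rows.append(
                    {"substance": substance, "N": N}
                    | {name: r[i] for i, name in enumerate(FEATURE_NAMES)}
                )
        return pd.DataFrame(rows)


def _ratio_vector(mut: np.ndarray, wt: np.ndarray, wt_floor: float) -> np.ndarray:
    out = np.empty(6)
    for i in range(6):
        # period (i=0) is always defined; strengths need to clear the
        # wildtype noise floor to make a meaningful quotient
        if i >= 1 and wt[i] < 3.0 * wt_floor:
            out[i] = np.nan
        else:
            out[i] = mut[i] / wt[i]
    return out


def mutant_experiment(
    wild_params,
    gene: str,
    Ns: Sequence[int] = (1, 2, 3, 4, 5),
    cfg: IntegrationConfig | None = None,
    n_periods: int = 2,
) -> MutantReport:
    """Run the N-copy mutant series and report feature ratios.

    The wildtype parameters must produce a steady cycle; each mutant is
    integrated with the same settings policy and its six features are
    divided by the wildtype's.  For the two-gene model both P and Q are
    reported (a mutation in P leaves Q's coarse features nearly fixed
    but reshapes its harmonics — the interaction fingerprint).
    """
    if isinstance(wild_params, SingleGeneParams):
        model = "single_gene"
        substances = ("E",)
    elif isinstance(wild_params, TwoGeneParams):
        model = "two_gene"
        substances = ("P", "Q")
    else:
        raise ConfigError("wild_params must be SingleGeneParams or TwoGeneParams")
    Ns = tuple(int(N) for N in Ns)

    def run(params):
        use_cfg = cfg if cfg is not None else auto_config(params)
        if model == "single_gene":
            traj = integrate_single_gene(params, use_cfg)
            return {"E": steady_cycle(traj, n_periods=n_periods)}
        P, Q = integrate_two_gene(params, use_cfg)
        cP, cQ = steady_cycle_pair(P, Q, n_periods=n_periods)
        return {"P": cP, "Q": cQ}

    wt_cycles = run(wild_params)  # raises if the wildtype has no steady cycle
    wt_feats: dict[str, FeatureVector] = {}
    wt_arrays: dict[str, np.ndarray] = {}
    wt_floors: dict[str, float] = {}
    for s in substances:
        spec = compute_spectrum(wt_cycles[s])
        wt_feats[s] = extract_features(spec, n_periods)
        wt_arrays[s] = wt_feats[s].as_array()
        wt_floors[s] = noise_floor(spec)

    ratios: dict[str, dict[int, np.ndarray]] = {s: {} for s in substances}
    regime_changes: list[tuple[int, str]] = []
    for N in Ns:
        mut = apply_copy_number(wild_params, MutantSpec(model=model, gene=gene, N=N))
        try:
            cycles = run(mut)
        except (FlatSignalError, NotConvergedError, IntegrationError) as err:
            regime_changes.append((N, f"{type(err).__name__}: {err}"))
            continue
        for s in substances:
            feat = extract_features(compute_spectrum(cycles[s]), n_periods)
            ratios[s][N] = _ratio_vector(feat.as_array(), wt_arrays[s], wt_floors[s])

    return MutantReport(
        model=model,
        gene=gene,
        Ns=Ns,
        wildtype=wt_feats,
        ratios=ratios,
        regime_changes=regime_changes,
    )
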
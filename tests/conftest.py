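"""Shared fixtures: the worked-example parameter sets and their steady
cycles (session-scoped — the DDE integrations are the expensive part)."""

import numpy as np
import pytest

import oscspec as osc


@pytest.fixture(scope="session")
def printed_single_params() -> osc.SingleGeneParams:
    """Single-gene parameters of the worked matching example."""
    return osc.SingleGeneParams(alpha_E=1.0, beta_E=0.4, n_E=3, delta_E=5.0, k_E=0.4)


@pytest.fixture(scope="session")
def printed_two_params() -> osc.TwoGeneParams:
    """Two-gene parameters of the worked matching example."""
    return osc.TwoGeneParams(
        V_P=1.5, V_Q=0.25, W_P=0.2, W_Q=0.2, k_P=0.4, k_Q=0.4, delta_P=5.0, delta_Q=5.0
    )


@pytest.fixture(scope="session")
def single_trajectory(printed_single_params):
    cfg = osc.auto_config(printed_single_params)
    return osc.integrate_single_gene(printed_single_params, cfg)


@pytest.fixture(scope="session")
def single_cycle(single_trajectory):
    return osc.steady_cycle(single_trajectory)


@pytest.fixture(scope="session")
def single_spectrum(single_cycle):
    return osc.compute_spectrum(single_cycle)


@pytest.fixture(scope="session")
def two_trajectories(printed_two_params):
    cfg = osc.auto_config(printed_two_params)
    return osc.integrate_two_gene(printed_two_params, cfg)


@pytest.fixture(scope="session")
def two_cycles(two_trajectories):
    P, Q = two_trajectories
    return osc.steady_cycle_pair(P, Q)


@pytest.fixture(scope="session")
def two_spectra(two_cycles):
    cP, cQ = two_cycles
    return osc.compute_spectrum(cP), osc.compute_spectrum(cQ)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
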
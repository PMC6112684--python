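"""Shared fixtures: presets and the cortico-striatal timing-grid runs.

The heavy ensemble runs (11 spike timings x 100 pairings, N = 1000 synapses
per initial state, both engines) are computed once per session and shared by
the tests that read different aspects of the same experiment (regime bands,
engine agreement, pathway blockade).
"""

from __future__ import annotations

import numpy as np
import pytest

from calstdp import load_preset
from calstdp.analytic import switch_prob_curves
from calstdp.dynamics import SimulationSettings, simulate
from calstdp.protocols import StimulationProtocol

# fixed seed for the ensemble runs backing the acceptance checks
ACCEPT_SEED = 7

FIG_GRID_MS = list(range(-25, 30, 5))  # 11 timings, -25 .. +25 ms


@pytest.fixture(scope="session")
def cortico():
    return load_preset("corticostriatal")


@pytest.fixture(scope="session")
def cortico_grid(cortico):
    """Per-timing switch-fraction curves from both engines.

    Returns {dt_ms: {"sim": {n: uds}, "ana": {n: uds}}} where ``uds`` maps
    pathway name -> (U, D) after ``n`` pairings.
    """
    settings = SimulationSettings.for_model(
        cortico, seed=ACCEPT_SEED, record_per_pairing=True
    )
    out = {}
    for dt_ms in FIG_GRID_MS:
        protocol = StimulationProtocol(
            pattern="pair", dt=dt_ms / 1000.0, freq=1.0, n_pairings=100
        )
        res = simulate(cortico, protocol, settings)
        curves = switch_prob_curves(cortico, protocol)
        out[dt_ms] = {
            "sim": {n: res.uds_at(n) for n in range(1, 101)},
            "ana": {
                n: {name: (us[n], ds[n]) for name, (us, ds) in curves.items()}
                for n in range(1, 101)
            },
        }
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
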
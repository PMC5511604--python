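"""Shared fixtures: simulated study conditions are expensive, so each network
is simulated once per session and reused across detector/acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pulsewave import fixtures as fx
from pulsewave.solver import run_simulation

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

RIG_NAMES = ("rig-control", "rig-D24", "rig-D34", "rig-D44", "rig-D50")
CHAIN_NAMES = ("aorta-chain-healthy", "aorta-chain-AAA2")


@pytest.fixture(scope="session")
def catalogue():
    return fx.catalogue()


@pytest.fixture(scope="session")
def rig_results(catalogue):
    """name -> (catalogue entry, SimulationResult) for the five rig set-ups."""
    out = {}
    for name in RIG_NAMES:
        e = catalogue[name]
        out[name] = (e, run_simulation(e.build(), **e.sim_kwargs))
    return out


@pytest.fixture(scope="session")
def chain_results(catalogue):
    """name -> (entry, SimulationResult) for healthy and AAA-2 aortic chains."""
    out = {}
    for name in CHAIN_NAMES:
        e = catalogue[name]
        out[name] = (e, run_simulation(e.build(), **e.sim_kwargs))
    return out


@pytest.fixture()
def two_hump_forward():
    """Clean synthetic forward pressure pulse (kPa scale) on a 1 s record."""
    dt = 1e-3
    t = np.arange(0.0, 1.0, dt)

    def hump(c, w):
        y = np.cos(np.pi * (t - c) / (2 * w)) ** 2
        y[np.abs(t - c) > w] = 0.0
        return y

    from pulsewave.waves import Waveform

    vals = 1000.0 * (hump(0.22, 0.17) + 0.55 * hump(0.47, 0.18))
    return Waveform(vals, dt, quantity="pressure", units="Pa")
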
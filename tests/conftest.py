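"""Shared fixtures: reference cells, networks, and cached reference runs.

The expensive 60-s two-cell and single-cell reference simulations are
session-scoped so the event-classification, synchrony, and acceptance
tests share one integration each.
"""

import numpy as np
import pytest
from hypothesis import settings

import pitnet as pn
from pitnet.netgen import CellNetwork

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: standard two-cell study: one intrinsic burster coupled to one spiker
TWO_CELL = CellNetwork(2, frozenset({(0, 1)}), types=("burster", "spiker"))

#: the fixed 20-cell structural network used for placement sweeps
NET20_CFG = pn.GenConfig(n=20, p=0.7, seed=42)


def _sim(g_c, seed=1):
    return pn.SimConfig(
        dt=0.5, t_end=60_000.0, t_transient=20_000.0, g_c=g_c, seed=seed
    )


@pytest.fixture(scope="session")
def two_cell_net():
    return TWO_CELL


@pytest.fixture(scope="session")
def net20():
    return pn.random_walk_network(NET20_CFG)


@pytest.fixture(scope="session")
def strong_pair():
    """Burster + spiker at g_c = 0.05 nS, 60 s, 20 s transient."""
    return pn.run_network(TWO_CELL, None, _sim(0.05))


@pytest.fixture(scope="session")
def weak_pair():
    """Burster + spiker at g_c = 0.005 nS (phase drift, no conversion)."""
    return pn.run_network(TWO_CELL, None, _sim(0.005))


@pytest.fixture(scope="session")
def uncoupled_burster():
    return pn.run_single_cell(pn.burster_params(), _sim(0.0))


@pytest.fixture(scope="session")
def uncoupled_spiker():
    return pn.run_single_cell(pn.spiker_params(), _sim(0.0))
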
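"""Shared fixtures: parameter sets and expensive steady-state simulations.

The long pre-runs are computed once per session and shared across the
acceptance tests; everything derives from the packaged parameter sets.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hipsccm as hp
from hipsccm import SPONTANEOUS, model
from hipsccm.simulate import packaged_steady_state, prerun

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return hp.load_parameters("paci2018-optimized")


@pytest.fixture(scope="session")
def baseline_params():
    return hp.load_parameters("paci2013-baseline")


@pytest.fixture(scope="session")
def spont_steady_state(params):
    """Spontaneous steady state after a full 800 s pre-run."""
    return prerun(params, SPONTANEOUS, model.default_initial_state(), 800.0)


@pytest.fixture(scope="session")
def spont_trace(params, spont_steady_state):
    """20 s spontaneous analysis window at the steady state (0.1 ms grid)."""
    return hp.simulate(params, SPONTANEOUS, spont_steady_state, 20.0,
                       t0=800.0)


@pytest.fixture(scope="session")
def paced_steady_state():
    """Packaged 1 Hz paced steady state (800 s pre-run product)."""
    return packaged_steady_state("paced-1hz")


@pytest.fixture(scope="session")
def spont_ap(spont_trace):
    return hp.ap_biomarkers(spont_trace)


@pytest.fixture(scope="session")
def spont_cat(spont_trace):
    return hp.cat_biomarkers(spont_trace)
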
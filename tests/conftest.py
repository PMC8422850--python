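"""Shared fixtures.

The calibrated stage models and the swap-suite results are expensive
(seconds to minutes of simulation), so they are computed once per
session and shared between the unit suites and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from avpvk.experiments import swap_suite
from avpvk.neuron import calibrate, preset


@pytest.fixture(scope="session")
def di_model():
    return preset("diestrus")


@pytest.fixture(scope="session")
def pro_model():
    return preset("proestrus")


@pytest.fixture(scope="session")
def di_cal(di_model):
    return calibrate(di_model)


@pytest.fixture(scope="session")
def pro_cal(pro_model):
    return calibrate(pro_model)


@pytest.fixture(scope="session")
def swap_results(di_cal, pro_cal):
    """Full hybrid comparison (F-I + rebound for every swap)."""
    return swap_suite(di_cal, pro_cal, dt_int=0.005)


@pytest.fixture(scope="session")
def vc_panels():
    """Recovered Boltzmann parameters per component and stage."""
    from avpvk.experiments import reproduce_vc_panels

    frames = {stage: reproduce_vc_panels(stage) for stage in ("diestrus", "proestrus")}

    def lookup(stage, component, measure):
        df = frames[stage]
        row = df[(df.component == component) & (df.measure == measure)]
        assert len(row) == 1
        return float(row.value.iloc[0])

    return lookup


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
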
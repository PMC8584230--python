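"""Shared fixtures: model configs and cached neuron simulations.

The two-compartment neuron runs are the expensive part of the suite
(20-cycle runs at dt = 0.025 ms), so they are computed once per session and
shared between the behavioral and acceptance tests.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import settings

from lpmod.analysis import burst_metrics, detect_spikes
from lpmod.config import clamp_model_from_config, load_packaged_config
from lpmod.neuron import SynapseSpec, simulate_neuron, table3_neuron_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clamp_doc():
    return load_packaged_config("table2_clamp_model")


@pytest.fixture(scope="session")
def ohmic_clamp(clamp_doc):
    return clamp_model_from_config(clamp_doc, mi_t_mode="ohmic")


@pytest.fixture(scope="session")
def ghk_clamp(clamp_doc):
    return clamp_model_from_config(clamp_doc, mi_t_mode="ghk_ca")


@lru_cache(maxsize=None)
def _neuron_run(variant: str, period: float):
    model = table3_neuron_model(variant=variant)
    syn = SynapseSpec(period=period)
    trace = simulate_neuron(model, syn, n_cycles=20, dt_ms=0.025,
                            record_stride=4, record_currents=True)
    spikes = detect_spikes(trace.v_axon, trace.t, threshold=-10.0)
    metrics = burst_metrics(spikes, syn, range(15, 19))
    return trace, spikes, metrics


@pytest.fixture(scope="session")
def neuron_run():
    """Cached (trace, spikes, last-four-cycle metrics) per (variant, period)."""
    return _neuron_run
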
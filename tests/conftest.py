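import numpy as np
import pytest

import twostage as ts


@pytest.fixture(scope="session")
def morph():
    """The fixed 40-branch morphology of the calibrated reference cell."""
    return ts.synth.reference_morphology()


@pytest.fixture(scope="session")
def reference(morph):
    return ts.reference_neuron(morph)


@pytest.fixture(scope="session")
def small_network_config():
    """A miniature microcircuit for fast structural tests."""
    from dataclasses import replace

    # per-neuron afferent drive (n_aff * p_aff ~ 25 active synapses) matches
    # the full-size network so encoding still reaches plasticity thresholds
    return replace(
        ts.NetworkConfig(),
        n_exc=60,
        n_fs=6,
        n_som=6,
        n_aff_per_memory=50,
        p_aff_exc=0.5,
        encode_duration_ms=500.0,
        recall_duration_ms=300.0,
    )
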
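"""Shared fixtures: expensive simulations are session-scoped."""

import numpy as np
import pytest

from ipsctailor.clamp import (
    make_outward_protocol,
    make_sodium_protocol,
    outward_solution,
    simulate_voltage_clamp,
    sodium_solution,
)
from ipsctailor.decomposition import build_component_matrix
from ipsctailor.model import build_baseline_model
from ipsctailor.synthetic import SyntheticCellSpec, synth_outward_trace


@pytest.fixture(scope="session")
def baseline_model():
    return build_baseline_model()


@pytest.fixture(scope="session")
def component_matrix(baseline_model):
    """Unit-scale component matrix of the outward protocol (clamp @ 298 K)."""
    return build_component_matrix(baseline_model)


@pytest.fixture(scope="session")
def sodium_clamp(baseline_model):
    """All-component simulation of the sodium protocol under its solution."""
    return simulate_voltage_clamp(
        baseline_model, make_sodium_protocol(), sodium_solution()
    )


@pytest.fixture(scope="session")
def outward_clamp(baseline_model):
    return simulate_voltage_clamp(
        baseline_model, make_outward_protocol(), outward_solution()
    )


@pytest.fixture(scope="session")
def synthetic_trace(component_matrix):
    """A noisy synthetic outward recording with known ground truth."""
    spec = SyntheticCellSpec(
        true_s={"I_Ks": 139.0, "I_NaCa": 3.32}, seed=42
    )
    return spec, synth_outward_trace(spec, component_matrix)
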
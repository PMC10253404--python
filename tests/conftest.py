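import numpy as np
import pandas as pd
import pytest

from flavocap import (
    AbundanceMatrix,
    SimulationConfig,
    default_design,
    generate_ground_truth,
    simulate_peptide_report,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down experiment used across the suite: 80 proteins, default
    binder fraction and enrichment, fixed seed."""
    return SimulationConfig(n_proteins=80, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_design():
    return default_design()


@pytest.fixture(scope="session")
def small_report(small_truth, small_design, small_config):
    return simulate_peptide_report(small_truth, small_design, small_config)


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    """Hand-built 3-protein x 6-sample matrix (two triplicate groups) with a
    protein absent from the whole control group."""
    cap = ["cap_1", "cap_2", "cap_3"]
    ctrl = ["ctrl_1", "ctrl_2", "ctrl_3"]
    abundance = pd.DataFrame(
        {
            "cap_1": [400.0, 100.0, 50.0],
            "cap_2": [380.0, 110.0, 60.0],
            "cap_3": [420.0, 90.0, 55.0],
            "ctrl_1": [100.0, 100.0, np.nan],
            "ctrl_2": [105.0, 95.0, np.nan],
            "ctrl_3": [95.0, 105.0, np.nan],
        },
        index=["P_enriched", "P_flat", "P_absent_ctrl"],
    )
    counts = abundance.notna().astype(int) * 3
    m = AbundanceMatrix(abundance=abundance, peptide_counts=counts)
    m.capture_samples = cap  # convenience attributes for tests
    m.control_samples = ctrl
    return m
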
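import numpy as np
import pytest

from coralpred import FRParams, assay_design, simulate_experiment


@pytest.fixture(scope="session")
def recovery_dataset():
    """One simulated dataset at 10x the tabulated assay layout with known
    truth (a=0.4, h=0.02), shared by the fitting tests."""
    design = assay_design("tabulated").scaled(10)
    truth = FRParams(a=0.4, h=0.02)
    data = simulate_experiment(
        design, {"small": truth, "large": truth}, mode="binomial", seed=20_260_101
    )
    return data, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A single copy of the 20-trial layout (deliberately information-poor)."""
    design = assay_design("tabulated")
    truth = FRParams(a=0.4, h=0.02)
    return (
        simulate_experiment(design, {"small": truth, "large": truth}, seed=7),
        truth,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
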
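import numpy as np
import pytest

import granulecology as g


@pytest.fixture(scope="session")
def default_sim():
    """One default-design simulated experiment shared across tests."""
    return g.simulate_experiment(g.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_frame():
    return g.SampleFrame.default_design()


@pytest.fixture()
def small_counts():
    return g.CountMatrix(
        ["A", "B", "C"], ["s1", "s2"], np.array([[2, 1], [3, 1], [5, 8]])
    )


def relative(values, taxa=None, samples=None):
    """Helper: build a RelativeAbundanceMatrix from raw positive values."""
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=0)
    taxa = taxa or [f"T{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return g.RelativeAbundanceMatrix(taxa, samples, values)
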
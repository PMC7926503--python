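import numpy as np
import pandas as pd
import pytest

from claudinlow import (
    ExpressionMatrix,
    SimulationConfig,
    load_cl_signature,
    simulate_study,
)


@pytest.fixture(scope="session")
def signature():
    return load_cl_signature()


@pytest.fixture(scope="session")
def small_study():
    """One shared 2-cohort study with a strongly planted CL subpopulation."""
    config = SimulationConfig(n_genes=120, n_samples=200, n_cohorts=2, seed=11)
    return simulate_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
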
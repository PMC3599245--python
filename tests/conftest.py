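import numpy as np
import pandas as pd
import pytest

from ripeshift.expression import ExpressionMatrix, NegativeControls
from ripeshift.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """400-gene simulated experiment with the default planted structure."""
    cfg = SimConfig(n_genes=400, seed=1)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noise_free_sim():
    """Noise-free simulation: planted fold changes are exact."""
    cfg = SimConfig(n_genes=300, noise_sd=0.0, seed=2)
    return simulate_experiment(cfg)


def make_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    """Tiny matrix helper: 2 treatments x 1 stage unless samples given."""
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    if samples is None:
        assert values.shape[1] % 2 == 0
        n = values.shape[1] // 2
        samples = [f"A_S_{r}" for r in range(1, n + 1)] + [f"B_S_{r}" for r in range(1, n + 1)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def toy_matrix():
    """3 genes, A=(1,2,3)-style toy groups at a single stage."""
    return make_matrix(
        [[10, 20, 30, 40, 50, 60],
         [100, 100, 100, 100, 100, 100],
         [80, 60, 40, 20, 10, 5]]
    )


@pytest.fixture
def flat_controls():
    def build(samples, mean=100.0):
        return NegativeControls({s: np.full(5, mean) for s in samples})
    return build
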
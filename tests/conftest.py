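import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from genegrid.dataio import ExpressionDataset
from genegrid.synthetic import SimulationConfig, generate_dataset


def make_dataset(matrix, labels, gene_ids=None, sample_ids=None, positive_class=None):
    matrix = np.asarray(matrix, dtype=float)
    g, n = matrix.shape
    return ExpressionDataset(
        matrix,
        gene_ids or [f"g{i}" for i in range(g)],
        sample_ids or [f"s{j}" for j in range(n)],
        labels,
        positive_class,
    )


@pytest.fixture
def tiny_ds():
    """3 genes x 4 samples, labels A,A,B,B; g0 up in A, g1 down in A, g2 flat."""
    return make_dataset(
        [[10.0, 11.0, 1.0, 2.0],
         [1.0, 2.0, 10.0, 11.0],
         [5.0, 5.0, 5.0, 5.0]],
        ["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def signal_ds():
    """Strong-signal simulated dataset shared by slower tests."""
    ds, truth = generate_dataset(
        SimulationConfig(n_genes=300, n1=20, n2=20, n_informative_up=10,
                         n_informative_down=10, effect_size=3.0, seed=11)
    )
    return ds, truth


@pytest.fixture(scope="session")
def null_ds():
    """No-signal simulated dataset (effect size 0)."""
    ds, truth = generate_dataset(
        SimulationConfig(n_genes=300, n1=15, n2=15, n_informative_up=0,
                         n_informative_down=0, effect_size=0.0, seed=5)
    )
    return ds, truth
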
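import numpy as np
import pytest

from grnfusion.data_io import (ExpressionDataset, GeneIndex, SteadyStateMatrix,
                               TimeSeriesExperiment)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """5 genes, 2 time courses of 8 points + 6 steady rows, positive values."""
    genes = GeneIndex(tuple(f"G{i + 1}" for i in range(5)))
    experiments = [
        TimeSeriesExperiment(np.arange(8, dtype=float),
                             rng.uniform(0.1, 2.0, size=(8, 5)))
        for _ in range(2)
    ]
    steady = SteadyStateMatrix(rng.uniform(0.1, 2.0, size=(6, 5)))
    return ExpressionDataset(genes, experiments, steady)
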
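import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pathmeta.io import ExpressionDataset

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_dataset(values, genes=None, samples=None, name="toy") -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionDataset(
        name=name, matrix=pd.DataFrame(values, index=genes, columns=samples)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_dataset(rng):
    """30 genes x 12 samples, log-scale-ish values spanning the filter thresholds."""
    values = rng.normal(8.0, 1.5, size=(30, 12))
    return make_dataset(values, name="random")
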
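import numpy as np
import pandas as pd
import pytest

from isletgcn import (
    CountMatrix,
    NormalizedMatrix,
    generate_islet_dataset,
    normalize,
    preset_config,
)


@pytest.fixture(scope="session")
def mouse_dataset():
    """Default mouse preset dataset shared by recovery tests."""
    return generate_islet_dataset(preset_config("mouse_adult", seed=1))


@pytest.fixture(scope="session")
def mouse_norm(mouse_dataset):
    return normalize(mouse_dataset.counts)


@pytest.fixture()
def tiny_counts():
    rng = np.random.default_rng(0)
    values = rng.integers(0, 20, size=(5, 4))
    return CountMatrix(
        pd.Index([f"g{i}" for i in range(5)]),
        pd.Index([f"c{j}" for j in range(4)]),
        values,
    )


def norm_from_values(values, genes=None, cells=None, **kwargs):
    """Build a NormalizedMatrix directly from a value array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(pd.Index(genes), pd.Index(cells), values, **kwargs)
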
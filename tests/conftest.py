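import numpy as np
import pytest

from refstab import CtMatrix, collapse_replicates, default_config, generate_ct_dataset
from refstab.stability import QuantityMatrix


def make_ct(values, genes=None, samples=None, groups=None) -> CtMatrix:
    """CtMatrix from a 2-D (collapsed) or 3-D array with auto-named axes."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(arr.shape[1])]
    return CtMatrix(list(genes), list(samples), arr, groups)


def random_ct(rng, n_genes, n_samples, base=20.0, spread=2.0) -> CtMatrix:
    vals = base + rng.uniform(-spread, spread, (n_genes, n_samples))
    return make_ct(vals)


def as_quantity(m: CtMatrix, eff: float = 2.0) -> QuantityMatrix:
    from refstab import to_relative_quantity

    return to_relative_quantity(m, eff)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default 11 x 23 x 4 synthetic dataset with its ground truth."""
    return generate_ct_dataset(default_config(seed=7))


@pytest.fixture(scope="session")
def collapsed_synthetic(synthetic_dataset):
    m, truth = synthetic_dataset
    return collapse_replicates(m), truth
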
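import logging

import numpy as np
import pandas as pd
import pytest

from coexmod import ExpressionDataset, ModulePartition
from coexmod.simulate import ModuleSpec, SimulationConfig, generate_dataset

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic default scenario (5 modules, 200 background genes, n=60)."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def truth_partition(default_dataset):
    _, truth = default_dataset
    return ModulePartition(truth.module_of.replace("background", "grey"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def two_group_dataset(rng, n_genes=50, n_a=5, n_b=5, shift=None):
    """Small REF/TEST1 dataset; ``shift`` adds a per-gene mean offset to TEST1."""
    a = rng.standard_normal((n_genes, n_a))
    b = rng.standard_normal((n_genes, n_b))
    if shift is not None:
        b = b + np.asarray(shift)[:, None]
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"A{j}" for j in range(n_a)] + [f"B{j}" for j in range(n_b)]
    expr = pd.DataFrame(np.hstack([a, b]), index=genes, columns=samples)
    cond = pd.Series(["REF"] * n_a + ["TEST1"] * n_b, index=samples)
    return ExpressionDataset(expr, cond)
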
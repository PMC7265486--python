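import numpy as np
import pandas as pd
import pytest

from synprio import factorization as fz
from synprio import synthetic_data as syn


@pytest.fixture(scope="session")
def small_truth():
    return syn.generate_ground_truth(
        n_targets=4, n_pathways=11, n_genes=60, effect_sd=1.0, sparsity=0.2, seed=11
    )


@pytest.fixture(scope="session")
def small_panel(small_truth):
    return syn.generate_panel(
        small_truth, n_drugs=8, n_cells=60, noise_sd=0.2, missing_frac=0.1, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def interaction_6x11(rng):
    values = rng.normal(size=(6, 11))
    return fz.InteractionMatrix(
        values=pd.DataFrame(
            values,
            index=[f"T{i}" for i in range(6)],
            columns=[f"P{j}" for j in range(11)],
        )
    )
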
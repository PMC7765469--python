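import warnings

import numpy as np
import pandas as pd
import pytest

from pcdnet.diffexpr import CountMatrix
from pcdnet.simulate import SimConfig, simulate_experiment

# co-expression helpers warn when falling back to CPM; keep test output clean
warnings.filterwarnings("ignore", message="no gene lengths supplied")


@pytest.fixture(scope="session")
def null_experiment():
    """One 4v4 experiment with no planted effects (phi = 0.1)."""
    cfg = SimConfig(n_genes=500, n_experiments_death=1, n_experiments_stress=0,
                    replicates_per_arm=4, dispersion=0.1, seed=42,
                    lib_size_mean=1e6)
    return simulate_experiment(cfg, "death01")


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with hand-checkable CPM values."""
    df = pd.DataFrame({"s1": [10, 0, 90], "s2": [20, 0, 180]},
                      index=["g1", "g2", "g3"])
    return CountMatrix(df, library_sizes=pd.Series(
        {"s1": 1e6, "s2": 2e6}))


def factor_expression(n_genes, n_samples, members, loading, noise_sd, seed,
                      factor_sd=1.0):
    """Latent-factor expression matrix used across co-expression tests."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, (n_genes, n_samples))
    f = rng.normal(0.0, factor_sd, n_samples)
    for g in members:
        x[g] += loading * f
    return pd.DataFrame(x, index=[f"g{i:04d}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])
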
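import numpy as np
import pandas as pd
import pytest

from phosmod.synthetic import SyntheticConfig, generate_cohort


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A reduced cohort that exercises every stage quickly."""
    defaults = dict(
        n_samples=60,
        n_modules=4,
        module_size_range=(6, 15),
        n_noise_sites=60,
        n_decoy_regulators=6,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=0))


@pytest.fixture(scope="session")
def reduced_grid():
    grid = [("hdbscan", {"min_cluster_size": m}) for m in range(3, 11)]
    grid += [("kmeans", {"n_clusters": k}) for k in (4, 8)]
    grid += [("agglomerative", {"n_clusters": k}) for k in (4, 8)]
    return grid


@pytest.fixture()
def toy_matrix():
    """5 sites x 6 samples with one missing value."""
    idx = pd.MultiIndex.from_tuples(
        [("GA", "S1"), ("GB", "S2"), ("GC", "T3"), ("GD", "Y4"), ("GE", "S5")],
        names=["gene", "site"],
    )
    rng = np.random.default_rng(42)
    values = rng.normal(size=(5, 6))
    values[0, 2] = np.nan
    return pd.DataFrame(values, index=idx,
                        columns=[f"s{i}" for i in range(6)])
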
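import numpy as np
import pytest

from sdmeval import geodata, synthdata


@pytest.fixture(scope="session")
def small_stack() -> geodata.EnvStack:
    """Six independent autocorrelated layers on a 40 x 40 grid."""
    return synthdata.generate_env_stack(6, (40, 40), 2.0, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_stack) -> synthdata.SpeciesPool:
    return synthdata.generate_species_pool(
        small_stack, seed=7, record_counts=(6, 15, 40, 120))


def make_feature_table(n_pres: int, n_abs: int, seed: int = 0,
                       separation: float = 0.0,
                       columns: tuple[str, str] = ("v01", "v02"),
                       ) -> geodata.FeatureTable:
    """Synthetic two-variable feature table; ``separation`` shifts the
    first variable's mean for presences (large -> separable classes).
    Default column names match a two-layer stack from
    ``generate_env_stack(..., layer_prefix="v")``."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = n_pres + n_abs
    labels = np.concatenate([np.ones(n_pres, int), np.zeros(n_abs, int)])
    x1 = rng.normal(0, 1, n) + separation * labels
    x2 = rng.normal(0, 1, n)
    cells = np.column_stack([np.arange(n) // 50, np.arange(n) % 50])
    return geodata.FeatureTable(
        features=pd.DataFrame({columns[0]: x1, columns[1]: x2}),
        labels=labels, cells=cells)
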
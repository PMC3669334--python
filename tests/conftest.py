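import numpy as np
import pandas as pd
import pytest

from tissuespec import ExpressionDataset, SimulationConfig, TissueSampleMap, generate_pair
from tissuespec.synthetic import tissue_sample_maps


def make_dataset(values: dict[str, list[float]], symbols: list[str],
                 feature_ids: list[str] | None = None,
                 label: str = "test") -> ExpressionDataset:
    """Small in-memory dataset helper (columns = samples)."""
    df = pd.DataFrame(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"probe{i}" for i in range(len(df))]
    df.index = pd.Index(feature_ids, name="ID_REF")
    return ExpressionDataset(
        species_label=label,
        values=df,
        gene_symbols=pd.Series(symbols, index=df.index, name="IDENTIFIER"),
    )


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 probes x 4 samples, two tissues with 2 replicates each."""
    return make_dataset(
        {
            "GSM1": [10.0, 1.0, 5.0],
            "GSM2": [20.0, 3.0, np.nan],
            "GSM3": [2.0, 100.0, 5.0],
            "GSM4": [4.0, 300.0, 5.0],
        },
        symbols=["GENEA", "GENEB", "GENEC"],
    )


@pytest.fixture
def tiny_map() -> TissueSampleMap:
    return TissueSampleMap({"kidney": ["GSM1", "GSM2"], "liver": ["GSM3", "GSM4"]})


@pytest.fixture(scope="session")
def small_pair():
    """A 400-gene synthetic species pair with its maps and truth."""
    cfg = SimulationConfig(n_genes=400, seed=11)
    ds_a, ds_b, truth = generate_pair(cfg)
    map_a, map_b = tissue_sample_maps(cfg)
    return cfg, ds_a, map_a, ds_b, map_b, truth


def random_mean_matrix(rng: np.random.Generator, n_features: int = 50,
                       tissues: tuple[str, ...] = ("t1", "t2", "t3", "t4", "t5", "t6")):
    from tissuespec import TissueMeanMatrix

    means = pd.DataFrame(
        rng.lognormal(4, 1, size=(n_features, len(tissues))),
        index=pd.Index([f"p{i}" for i in range(n_features)], name="ID_REF"),
        columns=list(tissues),
    )
    return TissueMeanMatrix(
        means=means,
        n_replicates=pd.DataFrame(2, index=means.index, columns=means.columns),
        gene_symbols=pd.Series([f"G{i}" for i in range(n_features)],
                               index=means.index),
    )
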
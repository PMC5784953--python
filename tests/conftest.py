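import numpy as np
import pandas as pd
import pytest

import topopath as tp


def make_dataset(X, y, genes=None) -> tp.ExpressionDataset:
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    samples = [f"s{j}" for j in range(X.shape[1])]
    return tp.ExpressionDataset(X, pd.Index(genes), pd.Index(samples), np.asarray(y))


@pytest.fixture(scope="session")
def toy_suite_raw():
    return tp.toy_pathway_suite(seed=0)


@pytest.fixture(scope="session")
def toy_suite(toy_suite_raw):
    return {r.pathway_id: tp.preprocess_topology(r) for r in toy_suite_raw}


@pytest.fixture(scope="session")
def small_null_data():
    cfg = tp.SyntheticConfig(n_genes=300, n1=20, n2=15, seed=7)
    return tp.generate_base_dataset(cfg)


@pytest.fixture(scope="session")
def small_universe():
    return [f"g{i:05d}" for i in range(300)]
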
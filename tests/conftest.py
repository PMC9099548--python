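import numpy as np
import pandas as pd
import pytest

import nodalsig as ns


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down 3-cluster cohort: 2,000 genes, modules 100/100/80."""
    cfg = ns.SimConfig(n_genes=2000, de_block_sizes=[100, 100, 80], seed=3)
    counts, meta = ns.simulate_counts(cfg)
    return cfg, counts, meta


@pytest.fixture(scope="session")
def small_expr(small_sim):
    _, counts, _ = small_sim
    return pd.DataFrame(ns.logcpm(counts), index=counts.gene_ids,
                        columns=counts.sample_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_counts(counts_array, aligned=None):
    """CountMatrix from a plain 2-D array with generated ids."""
    counts_array = np.asarray(counts_array)
    g = [f"g{i}" for i in range(counts_array.shape[0])]
    s = [f"s{j}" for j in range(counts_array.shape[1])]
    return ns.CountMatrix(counts_array, g, s, aligned)
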
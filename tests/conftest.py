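import warnings

import numpy as np
import pandas as pd
import pytest

from nutriconnect.preprocess import ExpressionDataset
from nutriconnect.synthetic import SyntheticConfig

warnings.filterwarnings("ignore", message="no significant DE genes")


@pytest.fixture
def small_config():
    """A compact but fully powered study configuration."""
    return SyntheticConfig(
        seed=11, n_genes=300, n_diseases=4, n_foods=8, n_drugs=4,
        datasets_per_entity=3, samples_per_arm=5, network_nodes=150,
        edges_per_new_node=2, module_size=10, n_pathways=20,
        pathway_size_range=(8, 25), n_synergy_pairs=1,
        frac_anti_foods=0.5, frac_corr_foods=0.125)


def make_dataset(values: np.ndarray, genes=None, name="ds") -> ExpressionDataset:
    """Wrap a (genes x [controls | cases]) array, split evenly."""
    n_genes, n_samples = values.shape
    half = n_samples // 2
    genes = genes or [f"g{i}" for i in range(1, n_genes + 1)]
    cols = [f"c{i}" for i in range(half)] + [f"t{i}" for i in range(half)]
    df = pd.DataFrame(values, index=genes, columns=cols)
    labels = pd.Series(["control"] * half + ["case"] * half, index=cols)
    return ExpressionDataset(values=df, labels=labels, name=name)
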
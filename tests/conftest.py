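import numpy as np
import pandas as pd
import pytest

from refgene_select.io import CountMatrix, CtTable


def make_count_matrix(array, conditions=None, gene_ids=None) -> CountMatrix:
    """Build a CountMatrix from a 2-D array (genes x samples)."""
    array = np.asarray(array)
    n_genes, n_samples = array.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    conditions = conditions or ["c1"] * n_samples
    design = pd.DataFrame(
        {"genotype": "GT1", "stage": list(conditions), "treatment": "none"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = pd.DataFrame(array, index=gene_ids, columns=sample_ids)
    return CountMatrix(counts=counts, design=design)


def make_ct_table(array, efficiency=1.0, gene_ids=None) -> CtTable:
    array = np.asarray(array, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(array.shape[0])]
    ct = pd.DataFrame(array, index=gene_ids,
                      columns=[f"s{j + 1}" for j in range(array.shape[1])])
    eff = pd.Series(efficiency, index=ct.index, dtype=float)
    return CtTable(ct=ct, efficiency=eff)


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """2 genes x 3 samples, two conditions."""
    return make_count_matrix([[10, 12, 11], [100, 90, 110]],
                             conditions=["A", "A", "B"])


@pytest.fixture
def quantities_4x5() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    return pd.DataFrame(np.exp(rng.normal(0, 0.5, (4, 5))),
                        index=list("abcd"), columns=[f"s{j}" for j in range(5)])
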
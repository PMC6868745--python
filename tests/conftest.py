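from __future__ import annotations

import numpy as np
import pytest

from reosig import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, labels=None, dataset_id="test"):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    return ExpressionMatrix(values, gene_ids, sample_ids, labels, dataset_id)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
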
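import warnings

import numpy as np
import pandas as pd
import pytest

from grnrewire import synth as gs
from grnrewire.preprocess import log_normalize

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_study():
    """One fully planted synthetic study (default conditions, seed 7)."""
    truth0 = gs.default_truth(seed=7)
    motif, ppi, regulon = gs.generate_priors(12, 80, 0.2, 0.3, seed=7)
    truth = gs.plant_perturbation(truth0, regulon=regulon)
    adata = gs.simulate_counts(truth, 150, 2000.0, seed=7, regulon=regulon)
    log_normalize(adata)
    return {
        "truth": truth,
        "motif": motif,
        "ppi": ppi,
        "regulon": regulon,
        "adata": adata,
    }


def random_bipartite_edges(rng, n_tfs, n_genes, p=0.5, weights=(0.5, 2.0)):
    A = (rng.random((n_tfs, n_genes)) < p) * rng.uniform(*weights, (n_tfs, n_genes))
    rows = [
        (f"t{i}", f"g{j}", A[i, j])
        for i in range(n_tfs)
        for j in range(n_genes)
        if A[i, j] > 0
    ]
    return pd.DataFrame(rows, columns=["tf", "gene", "weight"])


def set_partitions(nodes):
    """All set partitions of a node list (restricted growth strings)."""
    n = len(nodes)
    codes = []

    def rgs(k, m):
        if k == n:
            yield tuple(codes)
            return
        for c in range(m + 1):
            codes.append(c)
            yield from rgs(k + 1, max(m, c + 1))
            codes.pop()

    for code in rgs(0, 0):
        yield {nodes[i]: code[i] for i in range(n)}
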
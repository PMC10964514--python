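import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from glicomix import qc, sim


@pytest.fixture(scope="session")
def small_sim():
    """A small co-culture simulation shared across read-only tests."""
    pair = sim.make_genotypes(100, 0.1, seed=7)
    cfg = sim.default_config(n_cells=400, n_genes=800, n_snps=100,
                             tumor_fraction=0.15, seed=7)
    adata, acm, truth = sim.simulate_cells(pair, cfg)
    return pair, cfg, adata, acm, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, _, adata, _, _ = small_sim
    return qc.normalize(adata.copy())


@pytest.fixture()
def toy_adata():
    """Tiny deterministic matrix for boundary-condition tests."""
    x = np.array([[0, 2, 0, 1],
                  [1, 3, 2, 0],
                  [4, 0, 1, 2],
                  [2, 2, 2, 2],
                  [0, 0, 0, 5]], dtype=np.int32)
    var = pd.DataFrame({
        "symbol": ["MT-CO1", "RPL3", "GENE1", "GENE2", "GENE3"],
        "chrom": ["chr1"] * 5,
        "pos": [10, 20, 30, 40, 50],
    })
    var = var.set_index("symbol", drop=False).rename_axis(None)
    obs = pd.DataFrame({"barcode": [f"c{i}" for i in range(4)]},
                       index=[f"c{i}" for i in range(4)])
    adata = ad.AnnData(X=x.T.copy(), obs=obs, var=var)
    adata.uns["layer"] = "raw"
    return adata


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="window truncated")
        yield
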
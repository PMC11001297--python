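import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from dopavuln.simulate import SimConfig, generate_atlas


def make_adata(counts, symbols=None, condition=None, sample=None):
    """Small dense-count AnnData helper (nuclei x genes)."""
    counts = np.asarray(counts, dtype=np.int32)
    n, g = counts.shape
    symbols = list(symbols) if symbols is not None else [f"G{j}" for j in range(g)]
    var = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    var["is_mito"] = [s.lower().startswith("mt-") for s in symbols]
    var["is_ribo"] = [s.startswith(("Rps", "Rpl")) for s in symbols]
    obs = pd.DataFrame(index=pd.Index([f"bc{i}" for i in range(n)], name="barcode"))
    obs["condition"] = condition if condition is not None else ["intact"] * n
    obs["sample"] = sample if sample is not None else ["s1"] * n
    adata = AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata


@pytest.fixture
def toy_adata():
    # 4 nuclei x 5 genes, one mito and one ribo gene
    counts = np.array(
        [
            [9, 1, 0, 0, 0],
            [0, 0, 5, 5, 0],
            [2, 0, 1, 0, 7],
            [0, 0, 0, 0, 0],
        ]
    )
    return make_adata(counts, symbols=["Th", "mt-Nd1", "Rps1", "Slc6a3", "Malat1"])


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated atlas reused across read-only tests."""
    cfg = SimConfig(
        territory_sizes=(400, 400, 400),
        survival_fraction=(0.1, 0.5, 0.9),
        background_size=400,
        seed=42,
    )
    adata, truth = generate_atlas(cfg)
    return cfg, adata, truth
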
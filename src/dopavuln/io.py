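"""Reading and writing count matrices in the 10x-style Matrix Market triplet.

On disk the matrix is gene x nucleus with 1-based coordinates (the Matrix
Market convention); in memory we use the AnnData convention of nuclei as
observations and genes as variables, raw counts in ``.X`` and a ``counts``
layer, with ``is_mito`` / ``is_ribo`` flags derived from gene symbols.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["read_tenx_triplet", "write_tenx_triplet", "flag_gene_types", "TripletFormatError"]

MITO_REGEX = r"(?i)^mt-"
RIBO_REGEX = r"^Rp[sl]"


class TripletFormatError(ValueError):
    """Raised when the on-disk triplet is inconsistent."""


def flag_gene_types(
    var: pd.DataFrame, mito_regex: str = MITO_REGEX, ribo_regex: str = RIBO_REGEX
) -> pd.DataFrame:
    """Add is_mito / is_ribo flags from symbol patterns (configurable)."""
    var = var.copy()
    symbols = var.index.to_series().astype(str)
    var["is_mito"] = symbols.str.contains(mito_regex, regex=True).to_numpy()
    var["is_ribo"] = symbols.str.contains(ribo_regex, regex=True).to_numpy()
    return var


def write_tenx_triplet(adata: AnnData, path: str | Path) -> Path:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` +
    ``metadata.tsv`` under ``path``; the mtx is gene x nucleus, integer.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise TripletFormatError("refusing to write an empty matrix")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sp.csc_matrix(sp.csr_matrix(counts).T)  # genes x nuclei
    scipy.io.mmwrite(path / "matrix.mtx", mat, field="integer")
    feat = pd.DataFrame(
        {
            "gene_id": [f"SIMG{i:07d}" for i in range(adata.n_vars)],
            "symbol": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feat.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = adata.obs.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "barcode"})
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)
    return path


def read_tenx_triplet(path: str | Path) -> AnnData:
    """Read a triplet directory back into AnnData (nuclei x genes, CSR).

    Validates the mtx header against features/barcodes, rejects duplicate
    barcodes, and joins ``metadata.tsv`` (if present) by barcode.
    """
    path = Path(path)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (path / fname).exists():
            raise TripletFormatError(f"missing {fname} in {path}")
    mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))  # genes x nuclei
    feat = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if mat.shape[0] != len(feat):
        raise TripletFormatError(
            f"matrix.mtx declares {mat.shape[0]} genes but features.tsv has {len(feat)}"
        )
    if mat.shape[1] != len(barcodes):
        raise TripletFormatError(
            f"matrix.mtx declares {mat.shape[1]} nuclei but barcodes.tsv has {len(barcodes)}"
        )
    if barcodes.duplicated().any():
        dupes = barcodes[barcodes.duplicated()].tolist()[:3]
        raise TripletFormatError(f"duplicate barcodes: {dupes}")
    symbols = feat[1] if feat.shape[1] > 1 else feat[0]
    var = pd.DataFrame(index=pd.Index(symbols.astype(str), name="symbol"))
    if var.index.duplicated().any():
        raise TripletFormatError("duplicate gene symbols in features.tsv")
    var = flag_gene_types(var)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = path / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str})
        if "barcode" not in meta.columns:
            raise TripletFormatError("metadata.tsv lacks a 'barcode' column")
        meta = meta.set_index("barcode")
        missing = obs.index.difference(meta.index)
        if len(missing):
            raise TripletFormatError(f"{len(missing)} barcodes absent from metadata.tsv")
        obs = obs.join(meta, how="left")
    X = sp.csr_matrix(mat.T)
    if (X.data < 0).any() or not np.allclose(X.data, np.round(X.data)):
        raise TripletFormatError("counts must be non-negative integers")
    X = X.astype(np.int32)
    adata = AnnData(X=X, obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata
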
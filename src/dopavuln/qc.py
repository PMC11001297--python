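"""Quality control and dopaminergic selection.

The filtering protocol: drop listed nuisance genes (Malat1 by default), drop
genes detected in fewer than 10 nuclei, then drop nuclei by detected-gene
floor/ceiling (500 / 10,000 — the ceiling doubles as the doublet filter) and
by mitochondrial UMI percentage (> 5%).  Nucleus-level metrics are computed
on the gene set as loaded, before any gene removal, so a nucleus's gene
tally is not perturbed by the rare-gene filter.  Dopaminergic nuclei are
those with at least one raw count in Th or Slc6a3 (OR semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QCReport",
    "compute_qc_metrics",
    "filter_dataset",
    "select_dopaminergic",
    "EmptyResultError",
]


class EmptyResultError(ValueError):
    """A filter removed every nucleus (or every gene)."""


@dataclass
class QCReport:
    """Per-nucleus and per-gene QC metrics.

    ``nuclei`` columns: n_genes_detected, n_umis, percent_mito, percent_ribo
    (percentages of total UMIs, NaN for zero-count nuclei), zero_total flag.
    ``genes`` columns: n_nuclei_detected.
    """

    nuclei: pd.DataFrame
    genes: pd.DataFrame


def _counts(adata: AnnData) -> sp.csr_matrix:
    return sp.csr_matrix(adata.layers.get("counts", adata.X))


def compute_qc_metrics(adata: AnnData) -> QCReport:
    """Detection tallies and mito/ribo UMI percentages.

    Nuclei with zero total UMIs are flagged and get NaN percentages rather
    than a division error.
    """
    for col in ("is_mito", "is_ribo"):
        if col not in adata.var.columns:
            raise ValueError(f"gene flag {col!r} missing; run io.flag_gene_types first")
    X = _counts(adata)
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = np.asarray(X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    ribo = np.asarray(X[:, adata.var["is_ribo"].to_numpy()].sum(axis=1)).ravel()
    zero = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(zero, np.nan, 100.0 * mito / np.where(zero, 1.0, total))
        pct_ribo = np.where(zero, np.nan, 100.0 * ribo / np.where(zero, 1.0, total))
    nuclei = pd.DataFrame(
        {
            "n_genes_detected": n_genes,
            "n_umis": total.astype(np.int64),
            "percent_mito": pct_mito,
            "percent_ribo": pct_ribo,
            "zero_total": zero,
        },
        index=adata.obs_names,
    )
    genes = pd.DataFrame(
        {"n_nuclei_detected": np.asarray((X > 0).sum(axis=0)).ravel()},
        index=adata.var_names,
    )
    return QCReport(nuclei=nuclei, genes=genes)


def filter_dataset(
    adata: AnnData,
    report: QCReport | None = None,
    min_nuclei_per_gene: int = 10,
    min_genes: int = 500,
    max_genes: int = 10_000,
    max_pct_mito: float = 5.0,
    drop_genes: tuple[str, ...] = ("Malat1",),
) -> AnnData:
    """Apply the gene and nucleus filters; returns a filtered copy.

    Boundary semantics follow the protocol wording: genes present in *fewer
    than* ``min_nuclei_per_gene`` nuclei go; nuclei with detected genes
    *below* ``min_genes`` or *above* ``max_genes``, or percent_mito *above*
    ``max_pct_mito``, go (all boundaries inclusive-keep).
    """
    if report is None:
        report = compute_qc_metrics(adata)
    nuc = report.nuclei.loc[adata.obs_names]
    keep_nuc = (
        (nuc["n_genes_detected"] >= min_genes)
        & (nuc["n_genes_detected"] <= max_genes)
        & (nuc["percent_mito"].fillna(np.inf) <= max_pct_mito)
    ).to_numpy()
    keep_gene = ~adata.var_names.isin(drop_genes)
    detected = report.genes.loc[adata.var_names, "n_nuclei_detected"].to_numpy()
    keep_gene &= detected >= min_nuclei_per_gene
    if keep_nuc.sum() == 0:
        raise EmptyResultError("all nuclei removed by QC filters")
    if keep_gene.sum() == 0:
        raise EmptyResultError("all genes removed by QC filters")
    out = adata[keep_nuc, :][:, keep_gene].copy()
    out.uns["qc"] = {
        "n_nuclei_in": int(adata.n_obs),
        "n_nuclei_out": int(out.n_obs),
        "n_genes_in": int(adata.n_vars),
        "n_genes_out": int(out.n_vars),
        "params": {
            "min_nuclei_per_gene": min_nuclei_per_gene,
            "min_genes": min_genes,
            "max_genes": max_genes,
            "max_pct_mito": max_pct_mito,
            "drop_genes": list(drop_genes),
        },
    }
    return out


def select_dopaminergic(
    adata: AnnData,
    genes: tuple[str, ...] = ("Th", "Slc6a3"),
    min_count: int = 1,
) -> AnnData:
    """Keep nuclei with raw count >= ``min_count`` in ANY of ``genes``.

    Records the retained/input ratio per condition in ``.uns['da_selection']``.
    """
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ValueError(f"none of the selection genes {genes} present in the matrix")
    X = _counts(adata)
    cols = [adata.var_names.get_loc(g) for g in present]
    keep = np.zeros(adata.n_obs, dtype=bool)
    for c in cols:
        keep |= np.asarray(X[:, c].todense()).ravel() >= min_count
    if keep.sum() == 0:
        raise EmptyResultError("no dopaminergic nuclei found")
    ratios = {}
    if "condition" in adata.obs.columns:
        for cond, grp in adata.obs.groupby("condition", observed=True):
            mask = adata.obs_names.isin(grp.index)
            n_in = int(mask.sum())
            ratios[str(cond)] = float(keep[mask].sum() / n_in) if n_in else float("nan")
    out = adata[keep, :].copy()
    out.uns["da_selection"] = {
        "genes": list(present),
        "min_count": min_count,
        "n_in": int(adata.n_obs),
        "n_out": int(out.n_obs),
        "retained_ratio_by_condition": ratios,
    }
    return out
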
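"""Vulnerability and resilience gene modules.

Construction recipe: run Wilcoxon rank-sum differential expression for each
candidate cluster against all other intact dopaminergic nuclei; call a
cluster *vulnerable* when its normalized cell loss exceeds 0.9 and
*resilient* below 0.5; keep genes significantly upregulated (Bonferroni
p < 0.05 and average log2FC > 0.5) in EVERY qualifying cluster; rank by mean
average log2FC and truncate (top 20 vulnerability, top 8 resilience).
Nuclei are then scored against expression-matched control genes, and
per-cluster mean scores regressed against cell loss (square-root transform,
input clusters excluded) to ask whether the module predicts loss outside
the clusters that defined it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from anndata import AnnData
from scipy import stats as ss

from .stats import GroupTestResult, choose_and_run_tests

__all__ = [
    "de_wilcoxon",
    "GeneModule",
    "select_module_genes",
    "score_module",
    "compare_scores",
    "ScoreLossRegression",
    "RegressionFit",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)


def de_wilcoxon(
    adata_norm: AnnData,
    mask_target: np.ndarray,
    mask_reference: np.ndarray | None = None,
    logfc_threshold: float = 0.25,
    min_pct: float = 0.1,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression, target vs
    reference (default: all other nuclei).

    Genes are pre-filtered to max(pct_in, pct_out) >= ``min_pct`` and
    |avg_log2FC| >= ``logfc_threshold``; avg_log2FC compares back-transformed
    (expm1) means with pseudocount 1.  P-values use the normal approximation
    with tie correction and are Bonferroni-adjusted over the full gene
    universe (``universe_size``, default: all genes in the matrix).
    """
    mask_target = np.asarray(mask_target, dtype=bool)
    if mask_reference is None:
        mask_reference = ~mask_target
    mask_reference = np.asarray(mask_reference, dtype=bool) & ~mask_target
    if mask_target.sum() == 0 or mask_reference.sum() == 0:
        raise ValueError("both target and reference groups must be nonempty")
    universe = universe_size if universe_size is not None else adata_norm.n_vars
    Xt = _dense(adata_norm.X[mask_target, :])
    Xr = _dense(adata_norm.X[mask_reference, :])
    pct_in = (Xt > 0).mean(axis=0)
    pct_out = (Xr > 0).mean(axis=0)
    log2fc = np.log2((np.expm1(Xt).mean(axis=0) + 1.0) / (np.expm1(Xr).mean(axis=0) + 1.0))
    testable = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(log2fc) >= logfc_threshold)
    pvals = np.full(adata_norm.n_vars, np.nan)
    for j in np.flatnonzero(testable):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = ss.mannwhitneyu(Xt[:, j], Xr[:, j], alternative="two-sided", method="asymptotic")
        pvals[j] = p
    out = pd.DataFrame(
        {
            "avg_log2FC": log2fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p": pvals,
            "p_adj": np.minimum(pvals * universe, 1.0),
        },
        index=adata_norm.var_names,
    )
    return out[testable].sort_values("p")


@dataclass
class GeneModule:
    """A ranked gene list with its construction provenance."""

    name: str
    genes: list[str]
    mean_log2fc: pd.Series
    input_clusters: list
    cutoffs: dict = field(default_factory=dict)
    excluded_gene: str | None = None

    def __len__(self) -> int:
        return len(self.genes)


def select_module_genes(
    cluster_losses: pd.Series,
    de_by_cluster: dict,
    direction: str,
    loss_hi: float = 0.9,
    loss_lo: float = 0.5,
    p_adj_cutoff: float = 0.05,
    log2fc_cutoff: float = 0.5,
    top_n: int | None = None,
    exclude_gene: str | None = None,
) -> GeneModule:
    """Build a vulnerability (loss > ``loss_hi``) or resilience
    (loss < ``loss_lo``) module from per-cluster DE tables on intact nuclei.

    A gene qualifies only if it passes (p_adj < cutoff AND log2FC > cutoff)
    in *every* qualifying cluster; ranking is by descending mean log2FC with
    a lexicographic tie-break.  ``exclude_gene`` drops one named gene from
    the final list (the transporter-excluded sensitivity variant).
    """
    if direction == "vulnerability":
        qualifying = cluster_losses[cluster_losses > loss_hi].index.tolist()
        default_top = 20
    elif direction == "resilience":
        qualifying = cluster_losses[cluster_losses < loss_lo].index.tolist()
        default_top = 8
    else:
        raise ValueError("direction must be 'vulnerability' or 'resilience'")
    top_n = top_n if top_n is not None else default_top
    cutoffs = {
        "loss_hi": loss_hi,
        "loss_lo": loss_lo,
        "p_adj": p_adj_cutoff,
        "log2fc": log2fc_cutoff,
        "top_n": top_n,
    }
    if not qualifying:
        raise ValueError(f"no cluster passes the {direction} loss cutoff")
    missing = [c for c in qualifying if c not in de_by_cluster]
    if missing:
        raise KeyError(f"no DE table for qualifying clusters {missing}")
    per_cluster_pass = []
    for c in qualifying:
        de = de_by_cluster[c]
        ok = de[(de["p_adj"] < p_adj_cutoff) & (de["avg_log2FC"] > log2fc_cutoff)]
        per_cluster_pass.append(set(ok.index))
    common = set.intersection(*per_cluster_pass)
    if exclude_gene is not None:
        common.discard(exclude_gene)
    if not common:
        return GeneModule(
            name=direction, genes=[], mean_log2fc=pd.Series(dtype=float),
            input_clusters=qualifying, cutoffs=cutoffs, excluded_gene=exclude_gene,
        )
    mean_fc = pd.Series(
        {
            g: float(np.mean([de_by_cluster[c].loc[g, "avg_log2FC"] for c in qualifying]))
            for g in common
        }
    )
    # descending mean fold change; stable sort preserves the prior
    # lexicographic order as the tie-break
    ranked = mean_fc.sort_index().sort_values(ascending=False, kind="mergesort")
    genes = ranked.index.tolist()[:top_n]
    return GeneModule(
        name=direction,
        genes=genes,
        mean_log2fc=mean_fc.loc[genes],
        input_clusters=qualifying,
        cutoffs=cutoffs,
        excluded_gene=exclude_gene,
    )


def score_module(
    adata_norm: AnnData,
    module_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-above-background module score per nucleus.

    Genes are sliced into ``n_bins`` equal-frequency bins of average
    expression; for each module gene ``n_ctrl`` control genes are sampled
    (without replacement when the bin allows, otherwise with replacement and
    a warning) from its bin, excluding module genes; the score is
    mean(module expression) - mean(pooled control expression).  Positive
    scores mean expression above the matched population background.
    """
    missing = [g for g in module_genes if g not in adata_norm.var_names]
    if missing:
        raise KeyError(f"module genes absent from matrix: {missing}")
    if len(module_genes) == 0:
        raise ValueError("empty module")
    rng = np.random.default_rng(seed)
    X = adata_norm.X
    gene_mean = np.asarray(sp.csr_matrix(X).mean(axis=0)).ravel()
    means = pd.Series(gene_mean, index=adata_norm.var_names)
    n_bins_eff = min(n_bins, len(means))
    bins = pd.qcut(means.rank(method="first"), q=n_bins_eff, labels=False)
    module_set = set(module_genes)
    controls: set[str] = set()
    for g in module_genes:
        pool = bins.index[(bins == bins[g]) & ~bins.index.isin(module_set)].tolist()
        if len(pool) == 0:
            warnings.warn(f"no control candidates in the bin of {g}", stacklevel=2)
            continue
        if len(pool) < n_ctrl:
            warnings.warn(
                f"bin of {g} has {len(pool)} candidates < n_ctrl={n_ctrl}; "
                "sampling with replacement",
                stacklevel=2,
            )
            draw = rng.choice(pool, size=n_ctrl, replace=True)
        else:
            draw = rng.choice(pool, size=n_ctrl, replace=False)
        controls.update(draw.tolist())
    if not controls:
        raise ValueError("no control genes could be drawn")
    mod_idx = [adata_norm.var_names.get_loc(g) for g in module_genes]
    ctrl_idx = [adata_norm.var_names.get_loc(g) for g in sorted(controls)]
    Xc = sp.csc_matrix(X)
    mod_mean = np.asarray(Xc[:, mod_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(Xc[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(mod_mean - ctrl_mean, index=adata_norm.obs_names, name="score")


def compare_scores(scores: pd.Series, groups: pd.Series, alpha: float = 0.05) -> GroupTestResult:
    """Module-score comparison across groups (both omnibus tests, then
    Conover-Iman post hocs when more than two groups)."""
    aligned = pd.DataFrame({"score": scores, "group": groups}).dropna()
    by_group = {g: d["score"].to_numpy() for g, d in aligned.groupby("group", observed=True)}
    return choose_and_run_tests(by_group, alpha=alpha, always_both_omnibus=True)


@dataclass
class RegressionFit:
    """OLS fit of cell loss on (transformed) module score."""

    slope: float
    intercept: float
    r_squared: float
    model_p: float
    conf_int: pd.DataFrame
    excluded_clusters: list
    transform: str
    n: int
    results: object | None = None

    def summary(self) -> str:
        lines = [
            "Cell loss ~ module score",
            "=" * 50,
            f"n clusters: {self.n} (excluded: {self.excluded_clusters})",
            f"transform: {self.transform}",
            f"loss = {self.intercept:.4f} + {self.slope:.4f} * score'",
            f"R^2 = {self.r_squared:.4f}, model p = {self.model_p:.3g}",
            "95% CI:",
            str(self.conf_int.round(4)),
        ]
        return "\n".join(lines)


class ScoreLossRegression:
    """statsmodels-backed regression of per-cluster loss on mean module
    score, excluding the module's input clusters."""

    def __init__(
        self,
        loss_by_cluster: pd.Series,
        score_by_cluster: pd.Series,
        exclude: list | None = None,
        transform: str = "sqrt",
    ):
        self.exclude = list(exclude) if exclude else []
        data = pd.DataFrame({"loss": loss_by_cluster, "score": score_by_cluster}).dropna()
        data = data[~data.index.isin(self.exclude)]
        if len(data) < 3:
            raise ValueError(f"need >= 3 clusters after exclusion, have {len(data)}")
        self.data = data
        if transform not in ("sqrt", "none"):
            raise ValueError("transform must be 'sqrt' or 'none'")
        self.transform = transform

    def fit(self) -> RegressionFit:
        x = self.data["score"].to_numpy(dtype=float)
        tag = self.transform
        if self.transform == "sqrt":
            if (x < 0).any():
                shift = -x.min() + 1e-6
                x = x + shift
                tag = f"sqrt(shift {shift:.3g})"
            x = np.sqrt(x)
        if np.ptp(x) == 0:
            raise ValueError("predictor has zero variance; slope undefined")
        y = self.data["loss"].to_numpy(dtype=float)
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        ci = pd.DataFrame(res.conf_int(), index=["intercept", "slope"], columns=["lo", "hi"])
        return RegressionFit(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            r_squared=float(res.rsquared),
            model_p=float(res.f_pvalue),
            conf_int=ci,
            excluded_clusters=self.exclude,
            transform=tag,
            n=len(self.data),
            results=res,
        )
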
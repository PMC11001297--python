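"""Ground-truth recovery runs: the full analysis chain on simulated data.

These functions execute the same stages as the pipeline driver but return
the quantities that can be checked against the planted truth — territory
loss estimates, module gene recovery, score/loss association — and are what
both the test suite and the reproduction script call.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .clustering import ClusterModel, normalize_log
from .loss import CellLossModel, compute_beta
from .modules import ScoreLossRegression, de_wilcoxon, score_module, select_module_genes
from .qc import compute_qc_metrics, filter_dataset, select_dopaminergic
from .simulate import SimConfig, SimTruth, generate_atlas

__all__ = ["prepare_clustered", "run_loss_recovery", "run_module_recovery"]


def prepare_clustered(config: SimConfig, analysis_seed: int = 0):
    """Simulate -> QC -> beta -> dopaminergic selection -> cluster.

    Returns (normalized AnnData, labels frame, truth, beta, ClusterModel);
    the labels frame has cluster, subcluster, condition columns and the
    majority planted territory per cluster is attached as a grouping map in
    ``labels.attrs['grouping']``.
    """
    adata, truth = generate_atlas(config)
    filtered = filter_dataset(adata, compute_qc_metrics(adata))
    cond = filtered.obs["condition"].value_counts()
    beta = compute_beta(int(cond.get("intact", 0)), int(cond.get("lesioned", 0)))
    da = select_dopaminergic(filtered)
    norm = normalize_log(da)
    cm = ClusterModel.fit(norm, seed=analysis_seed)
    labels = cm.labels_frame(norm.obs_names)
    labels["condition"] = norm.obs["condition"].to_numpy()
    terr = truth.nuclei.loc[norm.obs_names, "territory"].to_numpy()
    grouping = {
        int(c): int(g.mode().iloc[0])
        for c, g in pd.DataFrame({"cluster": labels["cluster"].to_numpy(), "territory": terr})
        .groupby("cluster")["territory"]
    }
    labels.attrs["grouping"] = grouping
    return norm, labels, truth, beta, cm


def run_loss_recovery(config: SimConfig, analysis_seed: int = 0) -> dict:
    """Estimate per-territory normalized loss and compare to planted truth."""
    norm, labels, truth, beta, _ = prepare_clustered(config, analysis_seed)
    res = CellLossModel.from_labels(
        labels, beta=beta, grouping=labels.attrs["grouping"]
    ).fit()
    estimated = {int(t): float(v) for t, v in res.units.items()}
    return {
        "beta": beta,
        "beta_true": truth.beta_true,
        "territory_loss": estimated,
        "true_loss": truth.true_loss,
        "max_abs_error": max(
            abs(estimated[t] - truth.true_loss[t]) for t in truth.true_loss if t in estimated
        ),
        "n_nuclei": int(norm.n_obs),
        "results": res,
    }


def run_module_recovery(
    config: SimConfig, analysis_seed: int = 0, score_seed: int = 0
) -> dict:
    """Build the vulnerability module from intact-nuclei DE, score it, and
    measure planted-gene recovery plus the score/loss association outside
    the input clusters."""
    norm, labels, truth, beta, _ = prepare_clustered(config, analysis_seed)
    res = CellLossModel.from_labels(labels, beta=beta).fit()
    A = res.clusters["A"].dropna()
    intact_mask = (labels["condition"] == "intact").to_numpy()
    intact = norm[intact_mask]
    intact_clusters = labels.loc[intact_mask, "cluster"].to_numpy()
    de = {}
    for c in A[(A > 0.9) | (A < 0.5)].index:
        m = intact_clusters == c
        if m.sum() == 0 or (~m).sum() == 0:
            continue
        de[c] = de_wilcoxon(intact, m)
    module = select_module_genes(A, de, "vulnerability")
    planted = set(truth.vulnerability_genes) | {"Slc6a3"}
    planted_fraction = (
        float(np.mean([g in planted for g in module.genes])) if module.genes else 0.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = score_module(norm, module.genes, seed=score_seed)
    per_cluster = scores.groupby(labels["cluster"]).mean()
    keep = [c for c in A.index if c not in module.input_clusters]
    grouping = labels.attrs["grouping"]
    planted_loss = pd.Series({c: truth.true_loss[grouping[c]] for c in keep})
    rho = float(spearmanr(per_cluster.loc[keep], planted_loss.loc[keep]).statistic)
    reg = ScoreLossRegression(A, per_cluster, exclude=module.input_clusters).fit()
    return {
        "module": module,
        "planted_fraction": planted_fraction,
        "spearman_score_vs_planted_loss": rho,
        "regression": reg,
        "cluster_loss": A,
        "per_cluster_score": per_cluster,
        "n_nuclei": int(norm.n_obs),
    }
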
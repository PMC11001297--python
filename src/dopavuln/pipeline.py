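"""End-to-end driver: simulate/read -> QC -> dopaminergic selection ->
clustering -> cell loss -> modules -> regression, with a JSON run report.

Every stage is seeded from one root seed (expanded to per-stage child
seeds), persists its intermediates under the output directory, and records
input/output dimensions so the report chains consistently.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import qc as tqc
from .clustering import ClusterModel, dendrogram_to_newick, normalize_log
from .loss import CellLossModel, compute_beta
from .modules import ScoreLossRegression, de_wilcoxon, score_module, select_module_genes
from .simulate import SimConfig, generate_atlas

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

# provenance notes for the dump of effective defaults: which values follow
# the study protocol this pipeline reimplements, and which are package choices
PARAM_PROVENANCE = {
    "min_nuclei_per_gene": "protocol default: genes in fewer than 10 nuclei removed",
    "min_genes": "protocol default: detected-gene floor 500",
    "max_genes": "protocol default: detected-gene ceiling 10,000 (doublet filter)",
    "max_pct_mito": "protocol default: mitochondrial UMI ceiling 5%",
    "drop_genes": "protocol default: Malat1 removed before analysis",
    "selection_genes": "protocol default: Th or Slc6a3 expression selects dopaminergic nuclei",
    "n_hvgs": "protocol default: top 1000 variable genes",
    "n_pcs": "protocol default: PCs 1..30",
    "subcluster_resolution": "protocol default: Louvain resolution 0.5 for subclusters",
    "loss_hi": "protocol default: vulnerable means normalized loss > 90%",
    "loss_lo": "protocol default: resilient means normalized loss < 50%",
    "de_logfc_threshold": "protocol default: DE log2FC prefilter 0.25",
    "de_min_pct": "protocol default: DE min detection fraction 0.1",
    "module_p_adj": "protocol default: Bonferroni-adjusted p < 0.05",
    "module_log2fc": "protocol default: average log2FC > 0.5",
    "top_n_vulnerability": "protocol default: top 20 genes",
    "top_n_resilience": "protocol default: top 8 genes",
    "alpha": "protocol default: alpha 0.05, pairwise rejection at adjusted p <= alpha/2",
    "score_bins": "package choice: 24 expression bins (scoring-function convention)",
    "score_n_ctrl": "package choice: 100 control genes per module gene",
    "kmeans_k": "package choice: ceil(n/500), floor 8, when not set",
    "k_neighbors": "package choice: 20 nearest neighbors for the SNN graph",
    "scale_target": "package choice: depth-normalization target 10,000",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Effective parameters for a full run; defaults follow the protocol
    wherever it states a value (see :data:`PARAM_PROVENANCE`)."""

    input_dir: str | None = None  # read a triplet; None -> simulate
    out_dir: str | None = None
    seed: int = 0
    sim: SimConfig | None = None
    # qc
    min_nuclei_per_gene: int = 10
    min_genes: int = 500
    max_genes: int = 10_000
    max_pct_mito: float = 5.0
    drop_genes: tuple[str, ...] = ("Malat1",)
    selection_genes: tuple[str, ...] = ("Th", "Slc6a3")
    selection_min_count: int = 1
    # clustering
    scale_target: float = 1e4
    n_hvgs: int = 1000
    n_pcs: int = 30
    kmeans_k: int | None = None
    k_neighbors: int = 20
    subcluster_resolution: float = 0.5
    # loss / modules
    grouping: dict | None = None  # cluster -> unit; None -> derive from truth
    alpha: float = 0.05
    loss_hi: float = 0.9
    loss_lo: float = 0.5
    de_logfc_threshold: float = 0.25
    de_min_pct: float = 0.1
    module_p_adj: float = 0.05
    module_log2fc: float = 0.5
    top_n_vulnerability: int = 20
    top_n_resilience: int = 8
    score_bins: int = 24
    score_n_ctrl: int = 100
    exclude_module_gene: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("territory_sizes", "survival_fraction", "libsize_lognormal_params",
                        "stress_territories"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            cfg.sim = SimConfig(**sim)
        return cfg

    def describe(self) -> dict:
        """Effective values with provenance notes (protocol vs package)."""
        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = {
                "value": getattr(self, f.name) if f.name != "sim" else None,
                "note": PARAM_PROVENANCE.get(f.name, "run input"),
            }
        return out


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and optionally writes) the
    run report.  Any stage failure raises :class:`PipelineError` tagged with
    the stage name."""
    cfg = config
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(["sim", "cluster", "score"], _child_seeds(cfg.seed, 3)))
    report: dict = {"seed": cfg.seed, "stages": [], "headline": {}}
    timing: dict = {}

    def record(stage: str, n_in: int, n_out: int, t0: float, **extra) -> None:
        report["stages"].append(
            {"stage": stage, "nuclei_in": n_in, "nuclei_out": n_out, **extra}
        )
        timing[stage] = round(time.perf_counter() - t0, 3)

    # ---- input ------------------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    if cfg.input_dir is not None:
        path = Path(cfg.input_dir)
        if not path.exists():
            raise PipelineError("input", f"input directory does not exist: {path}")
        try:
            adata = tio.read_tenx_triplet(path)
        except Exception as exc:
            raise PipelineError("input", str(exc)) from exc
    else:
        sim_cfg = cfg.sim or SimConfig(seed=seeds["sim"])
        adata, truth = generate_atlas(sim_cfg)
    record("input", int(adata.n_obs), int(adata.n_obs), t0, n_genes=int(adata.n_vars))

    # ---- qc ----------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        qc_report = tqc.compute_qc_metrics(adata)
        filtered = tqc.filter_dataset(
            adata,
            qc_report,
            min_nuclei_per_gene=cfg.min_nuclei_per_gene,
            min_genes=cfg.min_genes,
            max_genes=cfg.max_genes,
            max_pct_mito=cfg.max_pct_mito,
            drop_genes=tuple(cfg.drop_genes),
        )
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc
    cond_counts = filtered.obs["condition"].value_counts().to_dict()
    record(
        "qc", int(adata.n_obs), int(filtered.n_obs), t0,
        n_genes=int(filtered.n_vars), by_condition={k: int(v) for k, v in cond_counts.items()},
    )
    if out_dir:
        qc_report.nuclei.to_csv(out_dir / "qc_nuclei.csv")

    # ---- beta --------------------------------------------------------------
    try:
        beta = compute_beta(int(cond_counts.get("intact", 0)), int(cond_counts.get("lesioned", 0)))
    except Exception as exc:
        raise PipelineError("beta", str(exc)) from exc
    report["headline"]["beta"] = round(beta, 3)

    # ---- dopaminergic selection -------------------------------------------
    t0 = time.perf_counter()
    try:
        da = tqc.select_dopaminergic(
            filtered, genes=tuple(cfg.selection_genes), min_count=cfg.selection_min_count
        )
    except Exception as exc:
        raise PipelineError("selection", str(exc)) from exc
    record(
        "selection", int(filtered.n_obs), int(da.n_obs), t0,
        ratios=da.uns["da_selection"]["retained_ratio_by_condition"],
    )

    # ---- clustering --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        norm = normalize_log(da, scale_target=cfg.scale_target)
        cm = ClusterModel.fit(
            norm,
            n_hvgs=min(cfg.n_hvgs, norm.n_vars),
            d=cfg.n_pcs,
            k=cfg.kmeans_k,
            subcluster_resolution=cfg.subcluster_resolution,
            k_neighbors=cfg.k_neighbors,
            seed=seeds["cluster"],
        )
    except Exception as exc:
        raise PipelineError("clustering", str(exc)) from exc
    labels = cm.labels_frame(norm.obs_names)
    labels["condition"] = norm.obs["condition"].to_numpy()
    record("clustering", int(da.n_obs), int(len(labels)), t0, k=int(cm.params["k"]))
    if out_dir:
        labels.to_csv(out_dir / "labels.csv")
        pd.DataFrame(cm.centroids).to_csv(out_dir / "centroids.csv", index=False)
        (out_dir / "dendrogram.nwk").write_text(dendrogram_to_newick(cm.linkage))

    # ---- grouping (cluster -> territory-like unit) -------------------------
    grouping = cfg.grouping
    if grouping is None and truth is not None:
        tdf = pd.DataFrame(
            {"cluster": labels["cluster"].to_numpy(),
             "territory": truth.nuclei.loc[norm.obs_names, "territory"].to_numpy()}
        )
        grouping = {
            int(c): f"territory_{int(g.mode().iloc[0])}"
            for c, g in tdf.groupby("cluster")["territory"]
        }

    # ---- cell loss ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        loss_model = CellLossModel.from_labels(labels, beta=beta, grouping=grouping)
        loss_res = loss_model.fit()
    except Exception as exc:
        raise PipelineError("loss", str(exc)) from exc
    record("loss", int(len(labels)), int(len(labels)), t0,
           n_subclusters=int(len(loss_res.subclusters)))
    report["headline"]["cluster_loss"] = {
        str(c): (None if np.isnan(v) else round(float(v), 4))
        for c, v in loss_res.clusters["A"].items()
    }
    if loss_res.units is not None:
        report["headline"]["unit_loss"] = {
            str(u): (None if np.isnan(v) else round(float(v), 4))
            for u, v in loss_res.units.items()
        }
    if out_dir:
        loss_res.subclusters.to_csv(out_dir / "loss_subclusters.csv", index=False)
        loss_res.clusters.to_csv(out_dir / "loss_clusters.csv")

    # ---- modules -----------------------------------------------------------
    t0 = time.perf_counter()
    intact = norm[labels["condition"].to_numpy() == "intact"]
    intact_clusters = labels.loc[labels["condition"] == "intact", "cluster"].to_numpy()
    cluster_A = loss_res.clusters["A"]
    de_by_cluster: dict = {}
    modules: dict = {}
    module_report: dict = {}
    candidates = cluster_A[(cluster_A > cfg.loss_hi) | (cluster_A < cfg.loss_lo)].index
    try:
        for c in candidates:
            mask = intact_clusters == c
            if mask.sum() == 0 or (~mask).sum() == 0:
                continue
            de_by_cluster[c] = de_wilcoxon(
                intact, mask,
                logfc_threshold=cfg.de_logfc_threshold,
                min_pct=cfg.de_min_pct,
            )
        for direction, top_n in (
            ("vulnerability", cfg.top_n_vulnerability),
            ("resilience", cfg.top_n_resilience),
        ):
            try:
                mod = select_module_genes(
                    cluster_A.dropna(), de_by_cluster, direction,
                    loss_hi=cfg.loss_hi, loss_lo=cfg.loss_lo,
                    p_adj_cutoff=cfg.module_p_adj, log2fc_cutoff=cfg.module_log2fc,
                    top_n=top_n,
                    exclude_gene=cfg.exclude_module_gene if direction == "vulnerability" else None,
                )
            except (ValueError, KeyError) as exc:
                module_report[direction] = {"error": str(exc)}
                continue
            modules[direction] = mod
            module_report[direction] = {
                "genes": mod.genes,
                "input_clusters": [str(c) for c in mod.input_clusters],
            }
    except Exception as exc:
        raise PipelineError("modules", str(exc)) from exc
    record("modules", int(intact.n_obs), int(intact.n_obs), t0,
           n_de_tables=len(de_by_cluster))
    report["headline"]["modules"] = module_report
    if out_dir:
        (out_dir / "modules.json").write_text(json.dumps(module_report, indent=2))

    # ---- scoring + regression ---------------------------------------------
    t0 = time.perf_counter()
    regression_report: dict = {}
    if "vulnerability" in modules and len(modules["vulnerability"]):
        try:
            scores = score_module(
                norm, modules["vulnerability"].genes,
                n_bins=cfg.score_bins, n_ctrl=cfg.score_n_ctrl, seed=seeds["score"],
            )
            per_cluster_score = scores.groupby(labels["cluster"]).mean()
            reg = ScoreLossRegression(
                cluster_A, per_cluster_score,
                exclude=modules["vulnerability"].input_clusters,
            ).fit()
            regression_report = {
                "slope": round(reg.slope, 4),
                "intercept": round(reg.intercept, 4),
                "r_squared": round(reg.r_squared, 4),
                "model_p": float(f"{reg.model_p:.4g}"),
                "transform": reg.transform,
                "n_clusters": reg.n,
            }
            if out_dir:
                scores.to_csv(out_dir / "vulnerability_scores.csv")
        except (ValueError, KeyError) as exc:
            regression_report = {"error": str(exc)}
    record("score_regress", int(norm.n_obs), int(norm.n_obs), t0)
    report["headline"]["regression"] = regression_report

    report["timing_s"] = timing  # excluded from determinism comparisons
    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
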
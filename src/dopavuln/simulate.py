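"""Synthetic two-condition snRNA-seq data with known lesion ground truth.

The generator emulates the study design this package analyses: unilateral
6-OHDA-style lesioning of midbrain dopamine (mDA) neurons, followed by
fluorescence-activated nuclear sorting (FANS) of both hemispheres and
single-nucleus sequencing.  The emitted dataset has

* a hierarchy of dopaminergic *territories* subdivided into subpopulations
  (the analogue of neighborhoods), each with a private marker-gene program;
* negative-binomial counts with lognormal library-size variation, a
  mitochondrial UMI fraction, ribosomal genes and a highly expressed
  ``Malat1``-like lncRNA (so the QC filters have something to do);
* per-territory survival probabilities under lesioning;
* an asymmetric FANS capture rate between conditions (the source of the
  yield-normalization coefficient beta);
* a non-dopaminergic background population that backfills the sorted pool on
  the lesioned side, mimicking a sorter that collects a roughly constant
  number of nuclei per hemisphere regardless of how many mDA neurons died;
* a stress-shifted "mostly lesion" (ML) expression state in a fraction of
  surviving nuclei of the most vulnerable territory, with dopaminergic
  markers (Th / Slc6a3) shifted down;
* graded vulnerability and resilience gene programs whose per-territory
  expression scales with the planted cell loss, so that module scores carry
  information about loss even outside the clusters used to build a module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["SimConfig", "SimTruth", "generate_atlas", "recovery_config", "module_config"]

N_MITO_GENES = 13  # mouse mtDNA protein-coding gene count
N_RIBO_GENES = 20


class ConfigurationError(ValueError):
    """Raised for inconsistent or out-of-range simulation parameters."""


@dataclass
class SimConfig:
    """Parameters of the synthetic lesion experiment.

    Probabilities are in [0, 1]; log2 effect sizes are in log2 units.
    ``survival_fraction[t]`` is the probability that a dopaminergic nucleus of
    territory ``t`` survives lesioning; planted loss is ``1 - survival``.
    ``yield_factor_*`` are FANS capture probabilities per condition; their
    ratio is the ground-truth yield coefficient ``beta_true``.
    """

    n_territories: int = 3
    territory_sizes: tuple[int, ...] = (800, 800, 800)
    n_subpops_per_territory: int = 2
    n_genes: int = 2000
    n_marker_genes_per_territory: int = 30
    marker_log2fc: float = 2.0
    survival_fraction: tuple[float, ...] = (0.05, 0.5, 0.9)
    yield_factor_intact: float = 0.9
    yield_factor_lesioned: float = 0.82
    ml_fraction: float = 0.4
    stress_gene_count: int = 30
    stress_log2fc: float = 2.0
    da_marker_downshift: float = 1.5
    nb_dispersion: float = 2.0
    libsize_lognormal_params: tuple[float, float] = (0.0, 0.35)
    mito_gene_fraction: float = 0.02
    n_samples_per_condition: int = 6
    seed: int = 0
    # plumbing beyond the headline design: background (non-dopaminergic)
    # population, subpopulation markers, graded vulnerability/resilience
    # programs.  background_size is the per-hemisphere non-DA pool before
    # lesion backfill; 0 disables the background entirely.
    background_size: int = 800
    n_background_marker_genes: int = 50
    n_subpop_marker_genes: int = 10
    subpop_log2fc: float = 1.0
    vulnerability_gene_count: int = 30
    vulnerability_log2fc: float = 1.0
    resilience_gene_count: int = 30
    resilience_log2fc: float = 1.0
    stress_territories: tuple[int, ...] | None = None
    mean_umi: float = 6000.0
    da_marker_mean: float = 12.0
    malat1_fraction: float = 0.07

    def __post_init__(self) -> None:
        if self.n_territories <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_territories and n_genes must be positive")
        if len(self.territory_sizes) != self.n_territories:
            raise ConfigurationError(
                f"territory_sizes has length {len(self.territory_sizes)}, "
                f"expected n_territories={self.n_territories}"
            )
        if any(s <= 0 for s in self.territory_sizes):
            raise ConfigurationError("territory sizes must be positive")
        if len(self.survival_fraction) != self.n_territories:
            raise ConfigurationError("survival_fraction must have one entry per territory")
        for p in self.survival_fraction:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"survival fraction {p} outside [0, 1]")
        for name in ("yield_factor_intact", "yield_factor_lesioned"):
            y = getattr(self, name)
            if not 0.0 < y <= 1.0:
                raise ConfigurationError(f"{name}={y} outside (0, 1]")
        if not 0.0 <= self.ml_fraction <= 1.0:
            raise ConfigurationError("ml_fraction outside [0, 1]")
        if not 0.0 <= self.mito_gene_fraction < 1.0:
            raise ConfigurationError("mito_gene_fraction outside [0, 1)")
        if self.n_subpops_per_territory <= 0 or self.n_samples_per_condition <= 0:
            raise ConfigurationError("counts must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")

    @property
    def beta_true(self) -> float:
        return self.yield_factor_intact / self.yield_factor_lesioned

    @property
    def true_loss(self) -> np.ndarray:
        return 1.0 - np.asarray(self.survival_fraction, dtype=float)


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated atlas."""

    nuclei: pd.DataFrame  # barcode-indexed: territory, subpop, condition, sample, stress
    territory_markers: dict[int, list[str]]
    subpop_markers: dict[str, list[str]]
    vulnerability_genes: list[str]
    resilience_genes: list[str]
    stress_genes: list[str]
    beta_true: float
    true_loss: dict[int, float]
    stress_territories: tuple[int, ...]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta_true": self.beta_true,
            "true_loss": {str(k): v for k, v in self.true_loss.items()},
            "territory_markers": {str(k): v for k, v in self.territory_markers.items()},
            "subpop_markers": self.subpop_markers,
            "vulnerability_genes": self.vulnerability_genes,
            "resilience_genes": self.resilience_genes,
            "stress_genes": self.stress_genes,
            "stress_territories": list(self.stress_territories),
            "seed": self.seed,
            "nuclei": self.nuclei.reset_index().to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))


def _gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign symbols, QC flags and program membership to genes."""
    n = cfg.n_genes
    needed = (
        N_MITO_GENES
        + N_RIBO_GENES
        + 3  # Malat1, Th, Slc6a3
        + cfg.n_marker_genes_per_territory * max(cfg.n_territories - 1, 0)
        + cfg.n_subpop_marker_genes * cfg.n_subpops_per_territory * cfg.n_territories
        + cfg.vulnerability_gene_count
        + cfg.resilience_gene_count
        + cfg.stress_gene_count
        + (cfg.n_background_marker_genes if cfg.background_size > 0 else 0)
    )
    if n < needed + 50:
        raise ConfigurationError(
            f"n_genes={n} too small for the configured programs (need >= {needed + 50})"
        )
    symbols = []
    for i in range(N_MITO_GENES):
        symbols.append(f"mt-Sim{i + 1}")
    for i in range(N_RIBO_GENES // 2):
        symbols.append(f"Rps{i + 1}s")
    for i in range(N_RIBO_GENES - N_RIBO_GENES // 2):
        symbols.append(f"Rpl{i + 1}s")
    symbols += ["Malat1", "Th", "Slc6a3"]
    n_rest = n - len(symbols)
    symbols += [f"Gene{i:05d}" for i in range(n_rest)]
    tbl = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    tbl["is_mito"] = tbl.index.str.lower().str.startswith("mt-")
    tbl["is_ribo"] = tbl.index.str.startswith(("Rps", "Rpl"))
    return tbl


def _base_means(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Per-gene baseline expected counts, scaled to cfg.mean_umi total."""
    mu = rng.lognormal(mean=0.0, sigma=1.25, size=len(genes))
    mito = genes["is_mito"].to_numpy()
    malat1 = genes.index == "Malat1"
    th = genes.index == "Th"
    dat = genes.index == "Slc6a3"
    special = mito | malat1 | th | dat
    # normalise the ordinary genes, then carve out the fixed UMI shares
    rest_share = 1.0 - cfg.mito_gene_fraction - cfg.malat1_fraction
    mu[special] = 0.0
    mu *= rest_share * cfg.mean_umi / mu.sum()
    mu[mito] = cfg.mito_gene_fraction * cfg.mean_umi / N_MITO_GENES
    mu[malat1] = cfg.malat1_fraction * cfg.mean_umi
    mu[th] = cfg.da_marker_mean
    mu[dat] = cfg.da_marker_mean / 2.0
    return mu


def generate_atlas(config: SimConfig) -> tuple[AnnData, SimTruth]:
    """Simulate a two-condition (intact / lesioned) nuclear atlas.

    Returns an :class:`~anndata.AnnData` with raw integer counts
    (nuclei x genes, CSR) plus per-nucleus and per-gene metadata, and the
    :class:`SimTruth` holding every planted quantity.  Fixed ``config.seed``
    reproduces the output exactly.

    Sampling model, per hemisphere: the lesion first thins each dopaminergic
    territory ``t`` with survival probability ``survival_fraction[t]`` (intact
    hemisphere: no thinning); the killed nuclei are replaced in the sorted
    tissue pool by non-dopaminergic background nuclei; FANS then captures
    every pooled nucleus independently with the per-condition yield factor.
    Marginally a territory contributes Binomial(size, survival x yield)
    nuclei on the lesioned side and Binomial(size, yield) on the intact side,
    while the *total* captured count has expectation yield x pool for both
    conditions, which is what makes the yield coefficient identifiable from
    QC totals.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_surv, rng_counts = [np.random.default_rng(s) for s in ss.spawn(3)]

    genes = _gene_table(cfg, rng_struct)
    base_mu = _base_means(cfg, genes, rng_struct)

    loss = cfg.true_loss
    most_vulnerable = int(np.argmax(loss))
    if cfg.stress_territories is None:
        stress_territories: tuple[int, ...] = (most_vulnerable,)
    else:
        stress_territories = tuple(cfg.stress_territories)

    # ---- gene program assignment -------------------------------------------
    free = [s for s in genes.index if s.startswith("Gene")]
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = free[cursor : cursor + k]
        cursor += k
        return out

    vulnerability_genes = take(cfg.vulnerability_gene_count)
    resilience_genes = take(cfg.resilience_gene_count)
    stress_genes = take(cfg.stress_gene_count)
    territory_markers: dict[int, list[str]] = {}
    for t in range(cfg.n_territories):
        if t == most_vulnerable:
            # the most vulnerable territory is marked by the vulnerability
            # program itself (its module genes are its signature)
            territory_markers[t] = list(vulnerability_genes)
        else:
            territory_markers[t] = take(cfg.n_marker_genes_per_territory)
    subpop_markers: dict[str, list[str]] = {}
    for t in range(cfg.n_territories):
        for j in range(cfg.n_subpops_per_territory):
            subpop_markers[f"{t}.{j}"] = take(cfg.n_subpop_marker_genes)
    background_markers = take(cfg.n_background_marker_genes) if cfg.background_size > 0 else []

    gene_index = {s: i for i, s in enumerate(genes.index)}

    # graded program weights: vulnerability tracks planted loss, resilience
    # tracks planted survival, both rescaled to [0, 1] across territories
    max_loss = float(loss.max()) if loss.max() > 0 else 1.0
    w_vuln = loss / max_loss
    surv = 1.0 - loss
    span = surv.max() - surv.min()
    w_res = (surv - surv.min()) / span if span > 0 else np.ones_like(surv)

    def effect_vector(territory: int | None, subpop: int | None, stressed: bool) -> np.ndarray:
        """log2 fold-change vector for one expression profile."""
        eff = np.zeros(cfg.n_genes)
        if territory is None:  # background
            for s in background_markers:
                eff[gene_index[s]] += cfg.marker_log2fc
            eff[gene_index["Th"]] = -np.inf  # no dopaminergic markers
            eff[gene_index["Slc6a3"]] = -np.inf
            return eff
        for s in territory_markers[territory]:
            eff[gene_index[s]] += cfg.marker_log2fc if territory != most_vulnerable else 0.0
        for s in vulnerability_genes:
            eff[gene_index[s]] += cfg.vulnerability_log2fc * w_vuln[territory]
        for s in resilience_genes:
            eff[gene_index[s]] += cfg.resilience_log2fc * w_res[territory]
        # Slc6a3 is itself vulnerability-graded: the transporter that imports
        # the toxin is higher where loss is higher
        eff[gene_index["Slc6a3"]] += cfg.vulnerability_log2fc * w_vuln[territory]
        if subpop is not None:
            for s in subpop_markers[f"{territory}.{subpop}"]:
                eff[gene_index[s]] += cfg.subpop_log2fc
        if stressed:
            for s in stress_genes:
                eff[gene_index[s]] += cfg.stress_log2fc
            eff[gene_index["Th"]] -= cfg.da_marker_downshift
            eff[gene_index["Slc6a3"]] -= cfg.da_marker_downshift
        return eff

    # ---- nucleus bookkeeping ------------------------------------------------
    rows = []  # (territory or -1, subpop or -1, condition, stress)
    survivors_killed_total = 0
    for t, size in enumerate(cfg.territory_sizes):
        subpops_i = rng_struct.integers(0, cfg.n_subpops_per_territory, size=size)
        # intact hemisphere: capture only
        captured_i = rng_surv.random(size) < cfg.yield_factor_intact
        for j in subpops_i[captured_i]:
            rows.append((t, int(j), "intact", False))
        # lesioned hemisphere: survival thinning, then capture
        subpops_l = rng_struct.integers(0, cfg.n_subpops_per_territory, size=size)
        survived = rng_surv.random(size) < cfg.survival_fraction[t]
        survivors_killed_total += int(size - survived.sum())
        captured_l = survived & (rng_surv.random(size) < cfg.yield_factor_lesioned)
        stress_draw = rng_surv.random(size) < cfg.ml_fraction
        is_stress_territory = t in stress_territories
        for j, st in zip(subpops_l[captured_l], stress_draw[captured_l]):
            rows.append((t, int(j), "lesioned", bool(st and is_stress_territory)))
    if cfg.background_size > 0:
        n_bg_intact = int(rng_surv.binomial(cfg.background_size, cfg.yield_factor_intact))
        pool_lesioned = cfg.background_size + survivors_killed_total
        n_bg_lesioned = int(rng_surv.binomial(pool_lesioned, cfg.yield_factor_lesioned))
        rows += [(-1, -1, "intact", False)] * n_bg_intact
        rows += [(-1, -1, "lesioned", False)] * n_bg_lesioned

    obs = pd.DataFrame(rows, columns=["territory", "subpop", "condition", "stress"])
    if obs.empty:
        raise ConfigurationError("simulation produced no nuclei")
    # stable shuffle so conditions/territories are interleaved as in real data
    perm = rng_struct.permutation(len(obs))
    obs = obs.iloc[perm].reset_index(drop=True)
    # samples round-robin within condition (6 animals per condition by default)
    for cond in ("intact", "lesioned"):
        mask = obs["condition"] == cond
        k = int(mask.sum())
        obs.loc[mask, "sample"] = [
            f"{cond}_{i % cfg.n_samples_per_condition + 1}" for i in range(k)
        ]
    obs.index = pd.Index([f"BC{i:07d}" for i in range(len(obs))], name="barcode")

    # ---- counts -------------------------------------------------------------
    theta = cfg.nb_dispersion
    mu_ls, sigma_ls = cfg.libsize_lognormal_params
    libsize = rng_counts.lognormal(mean=mu_ls, sigma=sigma_ls, size=len(obs))
    profile_key = list(zip(obs["territory"], obs["subpop"], obs["stress"]))
    X = np.zeros((len(obs), cfg.n_genes), dtype=np.int32)
    order = np.arange(len(obs))
    for key in sorted(set(profile_key)):
        t, j, st = key
        idx = order[[pk == key for pk in profile_key]]
        eff = effect_vector(None if t == -1 else int(t), None if j == -1 else int(j), st)
        mu_g = base_mu * np.exp2(eff)
        mu_block = np.outer(libsize[idx], mu_g)  # nuclei x genes
        p = theta / (theta + mu_block)
        block = rng_counts.negative_binomial(theta, p)
        block[mu_block == 0.0] = 0
        X[idx, :] = block

    adata = AnnData(
        X=sp.csr_matrix(X),
        obs=obs.copy(),
        var=genes.copy(),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.uns["sim_seed"] = cfg.seed

    truth = SimTruth(
        nuclei=obs,
        territory_markers=territory_markers,
        subpop_markers=subpop_markers,
        vulnerability_genes=vulnerability_genes,
        resilience_genes=resilience_genes,
        stress_genes=stress_genes,
        beta_true=cfg.beta_true,
        true_loss={t: float(l) for t, l in enumerate(loss)},
        stress_territories=stress_territories,
        seed=cfg.seed,
    )
    return adata, truth


def recovery_config(seed: int = 1) -> SimConfig:
    """The bundled parameter-recovery condition: three equally sized
    territories (2000 nuclei each) with survival 0.05 / 0.5 / 0.9."""
    return SimConfig(
        n_territories=3,
        territory_sizes=(2000, 2000, 2000),
        survival_fraction=(0.05, 0.5, 0.9),
        n_subpops_per_territory=2,
        background_size=1500,
        seed=seed,
    )


def module_config(seed: int = 1) -> SimConfig:
    """The bundled module-recovery condition: six territories with graded
    loss, 30 planted vulnerability genes at log2FC 1.0."""
    return SimConfig(
        n_territories=6,
        territory_sizes=(900, 900, 900, 900, 900, 900),
        survival_fraction=(0.05, 0.35, 0.55, 0.7, 0.85, 0.95),
        n_subpops_per_territory=2,
        subpop_log2fc=0.5,  # neighborhood heterogeneity is subtler than territory programs
        vulnerability_gene_count=30,
        vulnerability_log2fc=1.0,
        background_size=1000,
        seed=seed,
    )
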
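"""The normalized cell-loss statistic.

For a subcluster with intact count ``s_i`` and lesioned count ``s_l``, the
loss is ``L = 1 - (beta * s_l) / s_i`` where ``beta`` is the yield
normalization coefficient (intact / lesioned totals over all QC-passing
nuclei; it absorbs the asymmetry of nuclear-sorting capture between
conditions).  ``L = 1`` means total loss, ``L = 0`` no loss; negative values
(an apparent *gain*, possible through sampling noise) are set to NA.  A
cluster's loss ``A`` is the unweighted mean of its non-NA subcluster losses,
and higher-level units (neighborhoods, territories) aggregate the same
subcluster values through a cluster -> unit grouping map.

The estimator is exposed statsmodels-style: build a :class:`CellLossModel`
from a per-nucleus label table (or straight from intact/lesioned count
pairs), call :meth:`~CellLossModel.fit`, and read estimates, group
comparisons and a summary table off the :class:`CellLossResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import GroupTestResult, choose_and_run_tests, conover_iman

__all__ = ["compute_beta", "subcluster_loss", "cluster_loss", "aggregate_loss",
           "CellLossModel", "CellLossResults"]

NA_REASONS = {
    "negative": "beta-scaled lesioned count exceeds intact count",
    "no_intact": "subcluster absent from the intact side",
}


def compute_beta(n_intact_qc: int, n_lesioned_qc: int) -> float:
    """Yield normalization coefficient: intact / lesioned QC-passing totals.

    Full precision is returned; round to 3 decimals for reporting.
    """
    if n_intact_qc <= 0 or n_lesioned_qc <= 0:
        raise ValueError(
            f"both counts must be positive (got {n_intact_qc}, {n_lesioned_qc})"
        )
    return n_intact_qc / n_lesioned_qc


def subcluster_loss(s_i: int, s_l: int, beta: float) -> float:
    """1 - (beta * s_l) / s_i, NA (NaN) when negative or s_i == 0."""
    if s_i < 0 or s_l < 0:
        raise ValueError("counts must be non-negative")
    if s_i == 0:
        return float("nan")
    L = 1.0 - (beta * s_l) / s_i
    return L if L >= 0 else float("nan")


def cluster_loss(subcluster_losses) -> float:
    """Unweighted mean over non-NA subcluster losses (NaN if none)."""
    arr = np.asarray(list(subcluster_losses), dtype=float)
    valid = arr[~np.isnan(arr)]
    return float(valid.mean()) if len(valid) else float("nan")


def aggregate_loss(
    loss_table: pd.DataFrame, grouping: dict, weighted: bool = False
) -> pd.Series:
    """Per-unit loss from subcluster values via a cluster -> unit map.

    ``loss_table`` needs columns cluster, loss, s_i; units inherit the mean
    (optionally s_i-weighted) of their member non-NA subcluster losses.
    """
    tab = loss_table.copy()
    missing = set(tab["cluster"].unique()) - set(grouping)
    if missing:
        raise KeyError(f"grouping does not cover clusters {sorted(missing)}")
    tab["unit"] = tab["cluster"].map(grouping)
    out = {}
    for unit, grp in tab.groupby("unit"):
        valid = grp.dropna(subset=["loss"])
        if valid.empty:
            out[unit] = float("nan")
        elif weighted:
            out[unit] = float(np.average(valid["loss"], weights=valid["s_i"]))
        else:
            out[unit] = float(valid["loss"].mean())
    return pd.Series(out, name="loss").sort_index()


class CellLossModel:
    """Normalized cell loss over a subcluster partition.

    Parameters
    ----------
    counts : DataFrame with columns subcluster, cluster, s_i, s_l
        Per-subcluster intact / lesioned nucleus counts.
    beta : float
        Yield normalization coefficient (see :func:`compute_beta`); computed
        over *all* QC-passing nuclei, before any dopaminergic selection.
    grouping : optional dict
        cluster -> neighborhood/territory map for aggregated losses.
    weighted : bool
        Use subcluster-size (s_i) weighted cluster means instead of the
        default unweighted formula.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        beta: float,
        grouping: dict | None = None,
        weighted: bool = False,
    ):
        required = {"subcluster", "cluster", "s_i", "s_l"}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts table must have columns {sorted(required)}")
        if beta <= 0:
            raise ValueError("beta must be positive")
        self.counts = counts.reset_index(drop=True).copy()
        self.beta = float(beta)
        self.grouping = dict(grouping) if grouping else None
        self.weighted = weighted

    @classmethod
    def from_labels(
        cls,
        labels: pd.DataFrame,
        beta: float,
        condition_col: str = "condition",
        grouping: dict | None = None,
        weighted: bool = False,
    ) -> "CellLossModel":
        """Build the subcluster count table from per-nucleus labels
        (columns: cluster, subcluster, condition with intact/lesioned)."""
        required = {"cluster", "subcluster", condition_col}
        if not required.issubset(labels.columns):
            raise ValueError(f"labels must have columns {sorted(required)}")
        tab = (
            labels.groupby(["cluster", "subcluster"], observed=True)[condition_col]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["intact", "lesioned"], fill_value=0)
            .reset_index()
            .rename(columns={"intact": "s_i", "lesioned": "s_l"})
        )
        return cls(tab, beta=beta, grouping=grouping, weighted=weighted)

    def fit(self) -> "CellLossResults":
        tab = self.counts.copy()
        tab["loss"] = [
            subcluster_loss(si, sl, self.beta) for si, sl in zip(tab["s_i"], tab["s_l"])
        ]
        reasons = []
        for si, sl, L in zip(tab["s_i"], tab["s_l"], tab["loss"]):
            if si == 0:
                reasons.append("no_intact")
            elif np.isnan(L):
                reasons.append("negative")
            else:
                reasons.append("")
        tab["na_reason"] = reasons
        rows = []
        for c, grp in tab.groupby("cluster"):
            if self.weighted:
                valid = grp.dropna(subset=["loss"])
                A = (
                    float(np.average(valid["loss"], weights=valid["s_i"]))
                    if len(valid)
                    else float("nan")
                )
            else:
                A = cluster_loss(grp["loss"])
            rows.append(
                {
                    "cluster": c,
                    "A": A,
                    "n_subclusters_total": len(grp),
                    "n_subclusters_used": int(grp["loss"].notna().sum()),
                    "s_i": int(grp["s_i"].sum()),
                    "s_l": int(grp["s_l"].sum()),
                }
            )
        per_cluster = pd.DataFrame(rows).set_index("cluster").sort_index()
        per_unit = None
        if self.grouping is not None:
            per_unit = aggregate_loss(tab, self.grouping, weighted=self.weighted)
        return CellLossResults(
            model=self,
            subclusters=tab,
            clusters=per_cluster,
            units=per_unit,
        )


@dataclass
class CellLossResults:
    """Fitted loss table plus comparison machinery."""

    model: CellLossModel
    subclusters: pd.DataFrame
    clusters: pd.DataFrame
    units: pd.Series | None = None

    @property
    def beta(self) -> float:
        return self.model.beta

    def unit_of(self, cluster) -> str | None:
        return None if self.model.grouping is None else self.model.grouping.get(cluster)

    def compare_across(
        self, level: str = "cluster", alpha: float = 0.05, posthoc_only: bool = False
    ) -> GroupTestResult:
        """Compare subcluster loss values across clusters or units."""
        tab = self.subclusters.dropna(subset=["loss"])
        if level == "cluster":
            grouped = {c: g["loss"].to_numpy() for c, g in tab.groupby("cluster")}
        elif level == "unit":
            if self.model.grouping is None:
                raise ValueError("no grouping map supplied")
            by_unit = tab.assign(unit=tab["cluster"].map(self.model.grouping))
            grouped = {u: g["loss"].to_numpy() for u, g in by_unit.groupby("unit")}
        else:
            raise ValueError("level must be 'cluster' or 'unit'")
        grouped = {k: v for k, v in grouped.items() if len(v) > 0}
        if posthoc_only:
            return conover_iman(grouped, alpha=alpha)
        return choose_and_run_tests(grouped, alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Normalized cell loss",
            "=" * 60,
            f"beta (yield coefficient): {self.beta:.3f}",
            f"subclusters: {len(self.subclusters)} "
            f"({int(self.subclusters['loss'].isna().sum())} NA)",
            "",
            "Per-cluster loss A (mean of non-NA subcluster losses):",
        ]
        for c, row in self.clusters.iterrows():
            a = "NA" if np.isnan(row["A"]) else f"{row['A']:.3f}"
            lines.append(
                f"  cluster {c}: A={a}  "
                f"(N={int(row['n_subclusters_used'])}/{int(row['n_subclusters_total'])}, "
                f"s_i={int(row['s_i'])}, s_l={int(row['s_l'])})"
            )
        if self.units is not None:
            lines += ["", "Per-unit loss:"]
            for u, v in self.units.items():
                val = "NA" if np.isnan(v) else f"{v:.3f}"
                lines.append(f"  {u}: {val}")
        return "\n".join(lines)
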
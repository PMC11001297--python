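"""Group-comparison statistics for loss values and module scores.

The battery mirrors a common neuroscience workflow: Shapiro-Wilk (or, for
groups larger than 5000, the D'Agostino skewness/kurtosis omnibus) for
normality; Levene (normal data) or Fligner-Killeen (otherwise) for variance
homogeneity; Kruskal-Wallis and Welch's ANOVA as omnibus tests for more than
two groups with Conover-Iman pairwise post hocs under Benjamini-Hochberg
adjustment; a two-sample t-test or Wilcoxon rank-sum for two groups.

Conover-Iman convention used throughout: one-sided p = P(T >= |t|) with
df = n - k, and the null is rejected when the BH-adjusted p <= alpha/2
(0.025 at the default alpha of 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "kruskal_wallis",
    "conover_iman",
    "welch_anova",
    "choose_and_run_tests",
    "composition_chisq",
]

NORMALITY_LARGE_N = 5000


@dataclass
class GroupTestResult:
    """Outcome of a group comparison: branch bookkeeping, omnibus tests,
    and the pairwise table (test, statistic, p_raw, p_adj, reject)."""

    groups: list[str]
    preliminary: dict = field(default_factory=dict)
    omnibus: dict = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    branch: str = ""
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    @property
    def any_rejection(self) -> bool:
        return bool(self.pairwise is not None and self.pairwise["reject"].any())


def _as_groups(values_by_group: dict) -> dict[str, np.ndarray]:
    out = {}
    for k, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) == 0:
            raise ValueError(f"group {k!r} has no (non-NA) observations")
        out[str(k)] = arr
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def kruskal_wallis(values_by_group: dict) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = _as_groups(values_by_group)
    H, p = ss.kruskal(*groups.values())
    return float(H), float(p)


def conover_iman(
    values_by_group: dict,
    p_adjust: str = "bh",
    alpha: float = 0.05,
) -> GroupTestResult:
    """Conover-Iman pairwise comparisons on pooled midranks.

    t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 (n-1-H)/(n-k) (1/n_i + 1/n_j)),
    with the ties-corrected H and S^2 = (sum r^2 - n(n+1)^2/4)/(n-1);
    one-sided p = P(T >= |t|) on n-k degrees of freedom, BH-adjusted within
    the family, rejected at adjusted p <= alpha/2.
    """
    groups = _as_groups(values_by_group)
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n = len(pooled)
    k = len(names)
    res = GroupTestResult(groups=names, alpha=alpha)
    if np.ptp(pooled) == 0:
        res.notes.append("all observations identical; statistic undefined, no rejections")
        res.pairwise = pd.DataFrame(
            {
                "group1": [a for a, _ in combinations(names, 2)],
                "group2": [b for _, b in combinations(names, 2)],
                "test": "conover-iman",
                "statistic": np.nan,
                "p_raw": np.nan,
                "p_adj": np.nan,
                "reject": False,
            }
        )
        res.omnibus["kruskal"] = {"H": np.nan, "p": np.nan}
        return res
    ranks = ss.rankdata(pooled)
    bounds = np.cumsum([0] + [len(groups[g]) for g in names])
    rbar = {
        g: ranks[bounds[i] : bounds[i + 1]].mean() for i, g in enumerate(names)
    }
    H, p_kw = ss.kruskal(*groups.values())
    res.omnibus["kruskal"] = {"H": float(H), "p": float(p_kw)}
    S2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = S2 * (n - 1 - H) / (n - k)
    df = n - k
    rows = []
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(scale * (1.0 / na + 1.0 / nb))
        t = (rbar[a] - rbar[b]) / se if se > 0 else np.nan
        p_one = float(ss.t.sf(abs(t), df)) if np.isfinite(t) else np.nan
        rows.append((a, b, float(t), p_one))
    table = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p_raw"])
    table.insert(2, "test", "conover-iman")
    if p_adjust.lower() in ("bh", "fdr_bh"):
        table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    elif p_adjust in (None, "none"):
        table["p_adj"] = table["p_raw"]
    else:
        raise ValueError(f"unsupported p_adjust {p_adjust!r}")
    table["reject"] = table["p_adj"] <= alpha / 2.0
    res.pairwise = table
    return res


def welch_anova(values_by_group: dict) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F and p) via pingouin."""
    import pingouin as pg

    groups = _as_groups(values_by_group)
    df = pd.DataFrame(
        {
            "value": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups), [len(v) for v in groups.values()]),
        }
    )
    out = pg.welch_anova(data=df, dv="value", between="group")
    pcol = "p_unc" if "p_unc" in out.columns else "p-unc"
    return float(out["F"].iloc[0]), float(out[pcol].iloc[0])


def _normality(arr: np.ndarray, alpha: float) -> tuple[bool | None, dict]:
    if len(arr) < 3 or np.ptp(arr) == 0:
        return None, {"test": "skipped", "reason": "n < 3 or constant"}
    if len(arr) > NORMALITY_LARGE_N:
        stat, p = ss.normaltest(arr)  # D'Agostino skewness/kurtosis omnibus
        name = "dagostino"
    else:
        stat, p = ss.shapiro(arr)
        name = "shapiro"
    return bool(p > alpha), {"test": name, "statistic": float(stat), "p": float(p)}


def choose_and_run_tests(
    values_by_group: dict,
    alpha: float = 0.05,
    always_both_omnibus: bool = False,
) -> GroupTestResult:
    """Decision-tree group comparison; every branch taken is recorded.

    Two groups: t-test when both pass normality, Wilcoxon rank-sum otherwise.
    More than two groups: Kruskal-Wallis (always), Welch's ANOVA when the
    parametric route is defensible or ``always_both_omnibus`` is set, then
    Conover-Iman post hocs.  Groups with n < 3 force the non-parametric
    branch (flagged).
    """
    groups = _as_groups(values_by_group)
    res = GroupTestResult(groups=list(groups), alpha=alpha)
    verdicts = {}
    forced_nonparam = False
    for g, arr in groups.items():
        ok, rec = _normality(arr, alpha)
        verdicts[g] = ok
        res.preliminary[f"normality_{g}"] = rec
        if ok is None:
            forced_nonparam = True
    all_normal = all(v for v in verdicts.values() if v is not None) and not forced_nonparam
    if forced_nonparam:
        res.notes.append("group with n < 3: normality skipped, non-parametric branch forced")
    vals = list(groups.values())
    if all_normal:
        stat, p = ss.levene(*vals)
        res.preliminary["variance"] = {"test": "levene", "statistic": float(stat), "p": float(p)}
    else:
        stat, p = ss.fligner(*vals)
        res.preliminary["variance"] = {"test": "fligner", "statistic": float(stat), "p": float(p)}
    homoscedastic = p > alpha

    if len(groups) == 2:
        (a, b), (xa, xb) = list(groups), vals
        if all_normal:
            tstat, tp = ss.ttest_ind(xa, xb, equal_var=homoscedastic)
            row = ("t-test" if homoscedastic else "welch-t", float(tstat), float(tp))
            res.branch = "parametric-2sample"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ustat, up = ss.ranksums(xa, xb)
            row = ("wilcoxon-ranksum", float(ustat), float(up))
            res.branch = "nonparametric-2sample"
        res.pairwise = pd.DataFrame(
            [(a, b, *row, row[2], row[2] <= alpha)],
            columns=["group1", "group2", "test", "statistic", "p_raw", "p_adj", "reject"],
        )
        return res

    H, p_kw = ss.kruskal(*vals)
    res.omnibus["kruskal"] = {"H": float(H), "p": float(p_kw)}
    try:
        F, p_w = welch_anova(groups)
        res.omnibus["welch_anova"] = {"F": float(F), "p": float(p_w)}
    except Exception as exc:  # tiny/degenerate groups
        res.notes.append(f"welch ANOVA unavailable: {exc}")
    post = conover_iman(groups, alpha=alpha)
    res.pairwise = post.pairwise
    res.branch = "omnibus+conover-iman"
    res.notes += post.notes
    return res


def composition_chisq(table: pd.DataFrame) -> dict:
    """Pearson chi-square of independence on an animal x cluster count table.

    Zero-margin rows/columns are dropped with a warning; no continuity
    correction is applied.
    """
    tab = pd.DataFrame(table).astype(float)
    zero_rows = tab.index[tab.sum(axis=1) == 0]
    zero_cols = tab.columns[tab.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping zero-margin rows {list(zero_rows)} / columns {list(zero_cols)}",
            stacklevel=2,
        )
        tab = tab.drop(index=zero_rows, columns=zero_cols)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2 after dropping zero margins")
    chi2, p, dof, expected = ss.chi2_contingency(tab.to_numpy(), correction=False)
    return {
        "statistic": float(chi2),
        "p": float(p),
        "dof": int(dof),
        "expected": pd.DataFrame(expected, index=tab.index, columns=tab.columns),
    }
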
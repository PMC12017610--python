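"""Bivariate feature-symptom association analysis.

Correlation matrices (Spearman or Pearson, pairwise complete), severity
dichotomization at the clinical cutoffs (MADRS >= 19, YMRS >= 20 for severe
depressive / manic symptoms), Mann-Whitney group-difference tests between
severity groups, and sex-stratified subgroup analyses with heat-plot export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MADRS_SEVERE_CUTOFF = 19
YMRS_SEVERE_CUTOFF = 20

MIN_PAIRS = 4  # minimum complete pairs per correlation cell


@dataclass
class CorrelationMatrix:
    """Feature x target correlation panel with per-cell effective n and
    two-sided p-values; cells with insufficient data or zero variance are
    NaN with a reason recorded."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n_effective: pd.DataFrame
    method: str
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_long(self, stratum: str = "overall") -> pd.DataFrame:
        """Tidy long format: feature, target, stratum, rho, n, p."""
        rows = []
        for feature in self.rho.index:
            for target in self.rho.columns:
                rows.append(
                    {
                        "feature": feature,
                        "target": target,
                        "stratum": stratum,
                        "rho": self.rho.loc[feature, target],
                        "n": self.n_effective.loc[feature, target],
                        "p": self.p_value.loc[feature, target],
                    }
                )
        return pd.DataFrame(rows)


def _cell(x: np.ndarray, y: np.ndarray, method: str):
    """(rho, p, n, reason) for one pairwise-complete cell."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < MIN_PAIRS:
        return np.nan, np.nan, n, "insufficient complete pairs"
    xv, yv = x[ok], y[ok]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return np.nan, np.nan, n, "zero variance"
    if method == "spearman":
        rho, p = stats.spearmanr(xv, yv)
    elif method == "pearson":
        rho, p = stats.pearsonr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), n, None


def correlation_matrix(
    table: pd.DataFrame,
    features: Sequence[str],
    targets: Sequence[str],
    method: str = "spearman",
) -> CorrelationMatrix:
    """Pairwise-complete correlation of each feature against each target.

    Spearman uses average ranks for ties (scipy's convention); p-values are
    two-sided. Cells with fewer than four complete pairs or a zero-variance
    column come out NaN with the reason recorded.
    """
    rho = pd.DataFrame(index=list(features), columns=list(targets), dtype=float)
    pval = rho.copy()
    neff = pd.DataFrame(0, index=list(features), columns=list(targets), dtype=int)
    reasons: dict[tuple[str, str], str] = {}
    for f in features:
        for t in targets:
            r, p, n, reason = _cell(
                table[f].to_numpy(dtype=float), table[t].to_numpy(dtype=float), method
            )
            rho.loc[f, t] = r
            pval.loc[f, t] = p
            neff.loc[f, t] = n
            if reason:
                reasons[(f, t)] = reason
    return CorrelationMatrix(rho=rho, p_value=pval, n_effective=neff,
                             method=method, reasons=reasons)


def adjust_p_values(corr: CorrelationMatrix, method: str = "fdr_bh") -> pd.DataFrame:
    """Optional multiple-testing correction (off by default in the pipeline;
    raw p-values are the primary output)."""
    from statsmodels.stats.multitest import multipletests

    flat = corr.p_value.to_numpy().ravel()
    ok = np.isfinite(flat)
    adjusted = np.full_like(flat, np.nan)
    if ok.any():
        adjusted[ok] = multipletests(flat[ok], method=method)[1]
    return pd.DataFrame(
        adjusted.reshape(corr.p_value.shape),
        index=corr.p_value.index,
        columns=corr.p_value.columns,
    )


def dichotomize_severity(
    madrs_total: float | None, ymrs_total: float | None
) -> tuple[bool | None, bool | None]:
    """(depressive severe, manic severe) at the clinical cutoffs
    MADRS >= 19 and YMRS >= 20; None when the total is missing."""

    def flag(total, cutoff):
        if total is None or (isinstance(total, float) and np.isnan(total)):
            return None
        return bool(total >= cutoff)

    return flag(madrs_total, MADRS_SEVERE_CUTOFF), flag(ymrs_total, YMRS_SEVERE_CUTOFF)


@dataclass(frozen=True)
class GroupDifference:
    """Mann-Whitney rank-sum comparison of a feature between two groups.
    U is oriented as 'number of (group1, group2) pairs with group1 > group2'
    (scipy convention with x = group1)."""

    u_statistic: float
    p_value: float
    median_group1: float
    median_group2: float
    n_group1: int
    n_group2: int
    method: str


def group_difference(
    table: pd.DataFrame, feature: str, grouping: str | pd.Series
) -> GroupDifference | None:
    """Two-sided Mann-Whitney U test of `feature` between the two levels of
    a boolean grouping (True = group1). Exact null distribution when both
    groups are small (<= 20) and tie-free, normal approximation with tie
    correction otherwise. Returns None (missing) for degenerate inputs."""
    flags = table[grouping] if isinstance(grouping, str) else grouping
    values = table[feature].to_numpy(dtype=float)
    ok = np.isfinite(values) & flags.notna().to_numpy()
    g1 = values[ok & flags.fillna(False).to_numpy().astype(bool)]
    g2 = values[ok & ~flags.fillna(True).to_numpy().astype(bool)]
    if g1.size < 2 or g2.size < 2:
        return None
    pooled = np.concatenate([g1, g2])
    if np.ptp(pooled) == 0:
        return None  # constant feature: no ordering information
    has_ties = np.unique(pooled).size < pooled.size
    exact = (g1.size <= 20 and g2.size <= 20) and not has_ties
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            g1, g2, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
    return GroupDifference(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_group1=float(np.median(g1)),
        median_group2=float(np.median(g2)),
        n_group1=int(g1.size),
        n_group2=int(g2.size),
        method="exact" if exact else "asymptotic",
    )


def subgroup_analysis(
    table: pd.DataFrame,
    features: Sequence[str],
    targets: Sequence[str],
    method: str = "spearman",
    by: str = "sex",
    min_stratum_n: int = 4,
) -> dict[str, CorrelationMatrix]:
    """Correlation matrices overall and per stratum of `by` (default sex),
    mirroring an overall/female/male heat-plot panel. Strata smaller than
    min_stratum_n are omitted with a warning."""
    out = {"overall": correlation_matrix(table, features, targets, method)}
    for level, sub in table.groupby(by, sort=True):
        if len(sub) < min_stratum_n:
            warnings.warn(
                f"stratum {level!r} has n={len(sub)} < {min_stratum_n}; omitted"
            )
            continue
        out[str(level)] = correlation_matrix(sub, features, targets, method)
    return out


def correlation_heatmap(
    corr: CorrelationMatrix, path: str | Path, title: str | None = None
) -> None:
    """Diverging heat plot of the correlation matrix, color scale fixed at
    [-1, 1]."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rho = corr.rho.astype(float)
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.9 * rho.shape[1], 1.0 + 0.42 * rho.shape[0])
    )
    im = ax.imshow(rho.to_numpy(), cmap="RdBu_r", vmin=-1.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(rho.shape[1]), rho.columns)
    ax.set_yticks(range(rho.shape[0]), rho.index)
    for i in range(rho.shape[0]):
        for j in range(rho.shape[1]):
            v = rho.iloc[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=f"{corr.method} rho")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
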
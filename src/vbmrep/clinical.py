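"""Demographic/clinical association layer.

Spearman correlation matrices (appropriate for the strongly right-skewed
CTQ scales), Mann-Whitney group comparisons with rank-biserial effect
sizes, and the 2x2 severe-maltreatment x diagnosis contingency analysis
(Pearson chi-squared without continuity correction, odds ratio with a Wald
log-OR confidence interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Severe/none-minimal maltreatment (rows) by HC/MDD diagnosis (columns)."""

    severe_hc: int
    severe_mdd: int
    none_hc: int
    none_mdd: int

    def __post_init__(self) -> None:
        for name in ("severe_hc", "severe_mdd", "none_hc", "none_mdd"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0")

    @property
    def counts(self) -> np.ndarray:
        return np.array(
            [[self.severe_hc, self.severe_mdd], [self.none_hc, self.none_mdd]]
        )


@dataclass
class AssociationReport:
    """A statistic with its p-value and effect size."""

    statistic_name: str
    statistic: float
    p: float
    effect_name: str
    effect: float
    ci: tuple[float, float] | None = None
    n1: int | None = None
    n2: int | None = None


def spearman_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise two-sided Spearman correlations across the given columns.

    Returns (rho, p) DataFrames; the diagonal is 1/0.  Constant columns
    yield NaN entries (flagged in the log) rather than an error.
    """
    cols = columns or list(table.select_dtypes("number").columns)
    if any(table[c].notna().sum() < 3 for c in cols):
        raise ValueError("each column needs at least 3 observations")
    k = len(cols)
    rho = np.eye(k)
    pvals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            if pair[cols[i]].nunique() < 2 or pair[cols[j]].nunique() < 2:
                logger.warning(
                    "constant column in pair (%s, %s): rho undefined",
                    cols[i],
                    cols[j],
                )
                r = p = np.nan
            else:
                r, p = stats.spearmanr(pair[cols[i]], pair[cols[j]])
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pvals, index=cols, columns=cols),
    )


def mann_whitney_rb(group1, group2) -> AssociationReport:
    """Mann-Whitney U with a rank-biserial effect size.

    Two-sided p from the normal approximation with tie correction; the
    rank-biserial correlation r = 2U/(n1*n2) - 1 is oriented so that
    positive values mean group1 tends to exceed group2.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)  # number of (g1 > g2) pairs, ties counted 1/2
    r = 2.0 * u / (g1.size * g2.size) - 1.0
    return AssociationReport(
        statistic_name="U",
        statistic=u,
        p=float(res.pvalue),
        effect_name="rank_biserial",
        effect=r,
        n1=g1.size,
        n2=g2.size,
    )


def chi2_or_ci(table: ContingencyTable2x2, conf: float = 0.95) -> AssociationReport:
    """Pearson chi-squared (1 df, no continuity correction), OR and Wald CI.

    The odds ratio is oriented as (severe&MDD * none&HC) / (severe&HC *
    none&MDD): the odds of MDD among severely maltreated relative to the
    none-to-minimal group.  The CI is exp(ln OR +/- z * SE) with
    SE = sqrt(1/a + 1/b + 1/c + 1/d).
    """
    counts = table.counts
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError("all row and column marginals must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    assert dof == 1

    a, b, c, d = (
        table.severe_hc,
        table.severe_mdd,
        table.none_hc,
        table.none_mdd,
    )
    if min(a, b, c, d) == 0:
        raise ValueError("odds ratio/CI undefined with a zero cell")
    oddsr = (b * c) / (a * d)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(0.5 + conf / 2.0) if conf != 0.95 else Z_95
    lo, hi = np.exp(np.log(oddsr) - z * se), np.exp(np.log(oddsr) + z * se)
    return AssociationReport(
        statistic_name="chi2",
        statistic=float(chi2),
        p=float(p),
        effect_name="odds_ratio",
        effect=float(oddsr),
        ci=(float(lo), float(hi)),
        n1=int(a + b),
        n2=int(c + d),
    )


def severe_by_diagnosis_table(table: pd.DataFrame) -> ContingencyTable2x2:
    """Build the severe/none x HC/MDD table from a subject table."""
    sub = table[table["extreme_group"].isin(["severe", "none_minimal"])]
    severe = sub["extreme_group"] == "severe"
    mdd = sub["diagnosis"] == "MDD"
    return ContingencyTable2x2(
        severe_hc=int((severe & ~mdd).sum()),
        severe_mdd=int((severe & mdd).sum()),
        none_hc=int((~severe & ~mdd).sum()),
        none_mdd=int((~severe & mdd).sum()),
    )


def group_comparison_table(
    table: pd.DataFrame, columns: list[str], group_col: str = "diagnosis"
) -> pd.DataFrame:
    """Mann-Whitney + rank-biserial comparisons of MDD vs HC per column."""
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"{group_col} must have exactly two levels, got {groups}")
    g1, g2 = groups[::-1]  # MDD first when levels are HC/MDD
    rows = []
    for col in columns:
        rep = mann_whitney_rb(
            table.loc[table[group_col] == g1, col].dropna(),
            table.loc[table[group_col] == g2, col].dropna(),
        )
        rows.append(
            {
                "variable": col,
                "group1": g1,
                "group2": g2,
                "U": rep.statistic,
                "p": rep.p,
                "rank_biserial": rep.effect,
                "n1": rep.n1,
                "n2": rep.n2,
            }
        )
    return pd.DataFrame(rows)
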
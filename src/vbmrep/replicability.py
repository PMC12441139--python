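"""Cross-cohort replicability: conjunction overlap, Dice, permutation nulls.

A voxel "replicates" across a combination of cohorts when it is significant
(at the same uncorrected threshold) in every cohort of the combination.
Observed overlap counts are tested against a permutation null distribution
obtained by permuting the tested predictor independently within each cohort
(covariates and images fixed) and recomputing the overlap; p-values use the
add-one estimator (1 + #{null >= observed}) / (1 + n_perm) and enter a
Benjamini-Hochberg FDR family of models x cohort-combinations (72 tests for
the 18-model grid over 4 combinations of 3 cohorts).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glm import DesignMatrix, SignificanceMap, _perm_tstats, bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortCombination:
    """An unordered subset of 2 or 3 cohort names."""

    cohorts: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.cohorts) not in (2, 3):
            raise ValueError("combinations must have 2 or 3 cohorts")
        if len(set(self.cohorts)) != len(self.cohorts):
            raise ValueError("duplicate cohort in combination")

    @property
    def is_pair(self) -> bool:
        return len(self.cohorts) == 2

    def label(self) -> str:
        return "-".join(self.cohorts)


def cohort_combinations(names: list[str] | tuple[str, ...]) -> list[CohortCombination]:
    """All pairs plus the full triple (4 combinations for 3 cohorts)."""
    names = list(names)
    combos = [
        CohortCombination(tuple(pair)) for pair in itertools.combinations(names, 2)
    ]
    if len(names) == 3:
        combos.append(CohortCombination(tuple(names)))
    return combos


@dataclass
class OverlapResult:
    """Conjunction overlap of one model in one cohort combination."""

    model_id: object
    combination: CohortCombination
    k_overlap: int
    dice: float | None
    alpha: float
    p_perm: float | None = None
    p_fdr: float | None = None
    n_perm: int | None = None
    seed: int | None = None


@dataclass
class PermutationNull:
    """Null overlap counts from within-cohort predictor permutations."""

    combination: CohortCombination
    counts: np.ndarray
    scheme: str = "within-cohort predictor permutation"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("null overlap counts must be >= 0")


def _as_bool(m) -> np.ndarray:
    values = m.values if isinstance(m, SignificanceMap) else np.asarray(m)
    return np.asarray(values, dtype=bool)


def overlap_count(maps) -> int:
    """Voxels significant in ALL provided maps (common mask required)."""
    arrays = [_as_bool(m) for m in maps]
    if len(arrays) < 2:
        raise ValueError("need at least two maps")
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"map shapes differ: {shape} vs {a.shape}")
    conj = arrays[0]
    for a in arrays[1:]:
        conj = conj & a
    return int(conj.sum())


def dice(a, b) -> float | None:
    """Dice overlap 2|A∩B| / (|A|+|B|); None (flagged) when both maps empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.warning("Dice undefined: both maps empty")
        return None
    return 2.0 * int((a & b).sum()) / (na + nb)


def conjunction_fpr(alpha: float, m_cohorts: int) -> float:
    """Effective per-voxel false-positive rate of an m-cohort conjunction.

    Under independent null cohorts a voxel passes the per-cohort threshold
    ``alpha`` in all ``m_cohorts`` cohorts with probability ``alpha**m``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_cohorts < 1:
        raise ValueError("m_cohorts must be >= 1")
    return alpha**m_cohorts


def permutation_overlap_test(
    cohort_data: dict[str, tuple[np.ndarray, DesignMatrix]],
    alpha: float,
    n_perm: int = 1000,
    seed: int | None = None,
    sidedness: str = "one_sided_negative",
    model_id: object = None,
) -> tuple[list[OverlapResult], dict[str, PermutationNull]]:
    """Permutation test of cross-cohort conjunction overlap for one model.

    ``cohort_data`` maps cohort name to ``(Y, design)`` on a common voxel
    grid.  For each of ``n_perm`` permutations the tested predictor is
    permuted independently within each cohort, every cohort's GLM is refit,
    maps are thresholded at uncorrected ``alpha`` and the overlap recounted.
    Returns per-combination results plus null distributions.
    """
    if seed is None:
        raise ValueError("permutation test requires an explicit seed")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives coarse p-values", stacklevel=2)

    names = list(cohort_data)
    rng = np.random.default_rng(seed)
    sig_obs: dict[str, np.ndarray] = {}
    sig_null: dict[str, np.ndarray] = {}
    for name in names:
        Y, design = cohort_data[name]
        df = design.df
        if sidedness == "one_sided_negative":
            crit = stats.t.ppf(alpha, df)
            extreme = lambda t: t < crit  # noqa: E731
        else:
            crit = stats.t.ppf(1 - alpha / 2.0, df)
            extreme = lambda t: np.abs(t) > crit  # noqa: E731
        x = design.X[:, design.test_idx]
        perms = np.empty((n_perm, x.size))
        for k in range(n_perm):
            perms[k] = x[rng.permutation(x.size)]
        t_obs = _perm_tstats(Y, design, x[None, :])[0]
        t_null = _perm_tstats(Y, design, perms)
        with np.errstate(invalid="ignore"):
            sig_obs[name] = extreme(t_obs) & np.isfinite(t_obs)
            sig_null[name] = extreme(t_null) & np.isfinite(t_null)

    results: list[OverlapResult] = []
    nulls: dict[str, PermutationNull] = {}
    for combo in cohort_combinations(names):
        members = combo.cohorts
        obs = overlap_count([sig_obs[m] for m in members])
        conj = sig_null[members[0]]
        for m in members[1:]:
            conj = conj & sig_null[m]
        null_counts = conj.sum(axis=1)
        p = float((1 + int((null_counts >= obs).sum())) / (1 + n_perm))
        d = dice(sig_obs[members[0]], sig_obs[members[1]]) if combo.is_pair else None
        results.append(
            OverlapResult(
                model_id=model_id,
                combination=combo,
                k_overlap=obs,
                dice=d,
                alpha=alpha,
                p_perm=p,
                n_perm=n_perm,
                seed=seed,
            )
        )
        nulls[combo.label()] = PermutationNull(
            combination=combo, counts=null_counts, seed=seed
        )
    return results, nulls


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone, capped at 1)."""
    return bh_adjust(pvals)


def attach_fdr(results: list[OverlapResult]) -> list[OverlapResult]:
    """FDR-adjust permutation p-values over one model x combination family."""
    with_p = [r for r in results if r.p_perm is not None]
    if with_p:
        adj = bh_adjust(np.array([r.p_perm for r in with_p]))
        for r, a in zip(with_p, adj):
            r.p_fdr = float(a)
    return results


def build_overlap_table(
    overlap_results: list[OverlapResult],
    combination_order: list[str] | None = None,
):
    """Wide replicability table: one row per model, k/Dice/p per combination.

    Missing cells are emitted as NA.  The permutation p-values in the input
    are expected to be FDR-adjusted already (see :func:`attach_fdr`) — both
    raw and adjusted columns are written when available.
    """
    import pandas as pd

    if combination_order is None:
        combination_order = []
        for r in overlap_results:
            lab = r.combination.label()
            if lab not in combination_order:
                combination_order.append(lab)
    model_ids = []
    for r in overlap_results:
        if r.model_id not in model_ids:
            model_ids.append(r.model_id)

    rows = []
    for mid in model_ids:
        row: dict = {"model": mid}
        for lab in combination_order:
            match = [
                r
                for r in overlap_results
                if r.model_id == mid and r.combination.label() == lab
            ]
            if match:
                r = match[0]
                row[f"{lab}_k"] = r.k_overlap
                row[f"{lab}_dice"] = r.dice if r.dice is not None else np.nan
                row[f"{lab}_p_perm"] = r.p_perm if r.p_perm is not None else np.nan
                row[f"{lab}_p_fdr"] = r.p_fdr if r.p_fdr is not None else np.nan
            else:
                for suffix in ("k", "dice", "p_perm", "p_fdr"):
                    row[f"{lab}_{suffix}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
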
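"""Mass-univariate general linear models over voxels or regional endpoints.

Each voxel (column of the response matrix) gets an ordinary-least-squares
fit of the same design matrix; the tested predictor's t statistic is
converted to a one-sided-negative or two-sided p-value and to a partial R²
effect size via ``t² / (t² + df)`` with residual degrees of freedom
``df = n - rank(X)``.  Thresholding supports uncorrected p, Bonferroni,
Benjamini-Hochberg FDR, and permutation max-T family-wise error control
(the tested predictor column is permuted, covariates held fixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

THRESHOLD_METHODS = ("uncorrected", "bonferroni", "maxT_permutation", "fdr")


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise invalid design matrices."""


@dataclass
class DesignMatrix:
    """Numeric design with named columns and a designated tested column."""

    X: np.ndarray
    names: list[str]
    test_idx: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DesignError("design must be 2-D (subjects x columns)")
        if len(self.names) != self.X.shape[1]:
            raise DesignError("names length must match column count")
        if not 0 <= self.test_idx < self.X.shape[1]:
            raise DesignError("test_idx out of range")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            collinear = _collinear_columns(self.X, self.names)
            raise DesignError(
                f"design is rank deficient (rank {rank} < {self.X.shape[1]}); "
                f"suspect columns: {collinear}; for single-sex subsamples use a "
                "sex-stratified model spec without the sex covariate"
            )
        if self.df < 1:
            raise DesignError(f"residual df {self.df} < 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns implicated in rank deficiency (diagnostic only)."""
    out = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            out.append(names[j])
    return out or list(names)


@dataclass
class StatMap:
    """Per-voxel OLS results for one model in one cohort (or pooled).

    Arrays are 1-D over in-mask voxels; ``valid`` flags voxels that could be
    fitted (zero-variance voxels are excluded, count in ``n_excluded``).
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    partial_r2: np.ndarray
    df: int
    sidedness: str
    model_id: object = None
    cohort: str | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.t)

    @property
    def n_voxels(self) -> int:
        return self.t.size

    @property
    def n_excluded(self) -> int:
        return int((~self.valid).sum())


@dataclass
class SignificanceMap:
    """Boolean significance over in-mask voxels, with full provenance."""

    values: np.ndarray
    method: str
    alpha: float
    model_id: object = None
    cohort: str | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.values.sum())


def fit_glm_voxelwise(Y: np.ndarray, design: DesignMatrix, sidedness: str) -> StatMap:
    """OLS per voxel; t, p, and partial R² for the tested design column.

    ``sidedness`` is ``one_sided_negative`` (p = P(T_df <= t), testing for
    negative association) or ``two_sided``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n:
        raise ValueError(f"response rows {Y.shape[0]} != design rows {design.n}")
    if sidedness not in ("one_sided_negative", "two_sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")

    X = design.X
    df = design.df
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    beta_all = pinv @ Y                       # p x V
    resid = Y - X @ beta_all
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    cii = XtX_inv[design.test_idx, design.test_idx]

    zero_var = np.ptp(Y, axis=0) == 0.0
    valid = ~zero_var
    n_excluded = int(zero_var.sum())
    if n_excluded:
        logger.warning("excluding %d zero-variance voxels from maps", n_excluded)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * cii)
        t = beta_all[design.test_idx] / se
    t[zero_var] = np.nan
    se[zero_var] = np.nan

    p = np.full(t.shape, np.nan)
    if sidedness == "one_sided_negative":
        p[valid] = stats.t.cdf(t[valid], df)
    else:
        p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df)
    pr2 = np.full(t.shape, np.nan)
    pr2[valid] = partial_r2_from_t(t[valid], df)

    return StatMap(
        beta=beta_all[design.test_idx],
        se=se,
        t=t,
        p=p,
        partial_r2=pr2,
        df=df,
        sidedness=sidedness,
        valid=valid,
    )


def partial_r2_from_t(t, df):
    """Partial R² from a t statistic: t² / (t² + df)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = np.asarray(t, dtype=float)
    out = t * t / (t * t + df)
    return out if out.ndim else float(out)


def absolute_threshold_mask(images: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Mask voxels whose across-subject mean exceeds ``threshold``.

    ``images`` is (subjects, ...) — a 4-D stack or a subjects x voxels
    matrix; the mask has the trailing shape.  With ``rule='all'`` semantics
    see :func:`absolute_threshold_mask_all`.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    images = np.asarray(images, dtype=float)
    mask = images.mean(axis=0) > threshold
    if not mask.any():
        raise ValueError(
            f"absolute threshold {threshold} leaves an empty mask; "
            "review the threshold against the image intensity scale"
        )
    return mask


def absolute_threshold_mask_all(images: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Stricter variant: every subject must exceed ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    images = np.asarray(images, dtype=float)
    mask = images.min(axis=0) > threshold
    if not mask.any():
        raise ValueError(
            f"absolute threshold {threshold} leaves an empty mask; "
            "review the threshold against the image intensity scale"
        )
    return mask


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.reshape(np.shape(pvals))


def _perm_tstats(
    Y: np.ndarray, design: DesignMatrix, perms: np.ndarray
) -> np.ndarray:
    """t statistics of the tested column for a batch of predictor permutations.

    Uses Frisch-Waugh-Lovell: covariates are residualized out of Y once; each
    permuted predictor is residualized against the (fixed) covariates, and the
    simple regression of residual Y on the residual predictor reproduces the
    full-model t exactly.  ``perms`` is (n_perm, n) of permuted predictor
    values; returns (n_perm, V).
    """
    X = design.X
    j = design.test_idx
    covars = np.delete(X, j, axis=1)
    df = design.df
    Q, _ = np.linalg.qr(covars)
    Yr = Y - Q @ (Q.T @ Y)                     # n x V
    Xr = perms - (perms @ Q) @ Q.T             # n_perm x n
    norms2 = np.einsum("ij,ij->i", Xr, Xr)
    num = Xr @ Yr                              # n_perm x V
    yss = np.einsum("ij,ij->j", Yr, Yr)        # V
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / norms2[:, None]
        rss = yss[None, :] - beta * num
        t = beta * np.sqrt(norms2)[:, None] / np.sqrt(rss / df)
    return t


def maxt_adjusted_p(
    Y: np.ndarray,
    design: DesignMatrix,
    sidedness: str,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Permutation max-T FWE-adjusted p-values for the tested column.

    The tested predictor column is permuted ``n_perm`` times (covariates and
    images fixed); the null distribution of the most extreme statistic across
    voxels yields adjusted p = (1 + #{null max >= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    x = design.X[:, design.test_idx]
    n = x.size
    perms = np.empty((n_perm, n))
    for k in range(n_perm):
        perms[k] = x[rng.permutation(n)]
    t_null = _perm_tstats(Y, design, perms)
    t_obs = _perm_tstats(Y, design, x[None, :])[0]

    if sidedness == "one_sided_negative":
        stat_null, stat_obs = -t_null, -t_obs
    else:
        stat_null, stat_obs = np.abs(t_null), np.abs(t_obs)
    max_null = np.nanmax(stat_null, axis=1)          # n_perm
    exceed = (max_null[:, None] >= stat_obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_perm)


def threshold_map(
    stat_map: StatMap,
    method: str,
    alpha: float,
    Y: np.ndarray | None = None,
    design: DesignMatrix | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SignificanceMap:
    """Threshold a StatMap; no cluster-extent criterion is applied.

    ``maxT_permutation`` needs the response matrix, design, n_perm and a
    seed (reproducibility contract).  Invalid (excluded) voxels are never
    significant.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown method {method!r}; expected {THRESHOLD_METHODS}")
    valid = stat_map.valid
    p = stat_map.p
    extra: dict = {}

    if method == "uncorrected":
        # alpha == 1 keeps every fitted voxel (p <= 1 by construction)
        sig = valid if alpha >= 1 else valid & (p < alpha)
    elif method == "bonferroni":
        m = int(valid.sum())
        sig = valid & (p < alpha / m)
        extra["m"] = m
    elif method == "fdr":
        adj = np.full(p.shape, np.nan)
        adj[valid] = bh_adjust(p[valid])
        sig = valid & (adj < alpha)
        extra["p_adjusted"] = adj
    else:  # maxT_permutation
        if Y is None or design is None:
            raise ValueError("maxT_permutation requires Y and design")
        if seed is None:
            raise ValueError("maxT_permutation requires an explicit seed")
        logger.info(
            "FWE control via permutation max-T (n_perm=%d); voxel-level FWE "
            "at alpha=%g", n_perm, alpha,
        )
        p_fwe = maxt_adjusted_p(Y, design, stat_map.sidedness, n_perm, seed)
        sig = valid & (p_fwe < alpha)
        extra["p_fwe"] = p_fwe
        extra["n_perm"] = n_perm

    sig = np.asarray(sig, dtype=bool)
    sig[~valid] = False
    return SignificanceMap(
        values=sig,
        method=method,
        alpha=alpha,
        model_id=stat_map.model_id,
        cohort=stat_map.cohort,
        seed=seed,
        extra=extra,
    )
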
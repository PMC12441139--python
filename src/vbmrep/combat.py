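"""Empirical-Bayes ComBat harmonization of scanner/batch effects.

Implements the classic parametric ComBat scheme: features are standardized
against a pooled model with batch indicators and declared biological
covariates; per-batch additive (location) and multiplicative (scale)
effects are estimated per feature and shrunk across features with a normal
prior on locations and an inverse-gamma prior on scales; data are then
batch-adjusted and re-scaled with the biological covariate effects
restored, so covariates named as "biological" (e.g. CTQ sum, age, sex,
TIV, diagnosis) keep their variance.

Data orientation is subjects x features throughout the public API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CombatError(ValueError):
    """Raised for invalid ComBat inputs (tiny batches, singular designs)."""


@dataclass
class CombatModel:
    """Fitted ComBat parameters.

    Location/scale estimates are in standardized units, per batch and
    feature; ``gamma_star``/``delta_star`` are their EB-shrunk versions.
    """

    batches: list
    covariate_names: list[str]
    grand_mean: np.ndarray          # (features,)
    beta_cov: np.ndarray            # (n_covariates, features)
    var_pooled: np.ndarray          # (features,)
    gamma_hat: np.ndarray           # (n_batch, features)
    delta_hat: np.ndarray           # (n_batch, features)
    gamma_star: np.ndarray          # (n_batch, features)
    delta_star: np.ndarray          # (n_batch, features)

    def __post_init__(self) -> None:
        if len(self.batches) < 1:
            raise CombatError("at least one batch required")
        if np.any(self.delta_star <= 0):
            raise CombatError("EB scale estimates must be positive")


def _design(batch_labels, batches, covariates):
    """One-hot batch design plus covariates (no separate intercept)."""
    batch_labels = np.asarray(batch_labels)
    B = np.column_stack([(batch_labels == b).astype(float) for b in batches])
    if covariates is not None and covariates.shape[1]:
        return np.column_stack([B, covariates])
    return B


def _check_covariates(covariates, names, n):
    if covariates is None:
        return np.empty((n, 0)), []
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if names is None:
        names = [f"cov{i}" for i in range(covariates.shape[1])]
    if covariates.shape[0] != n:
        raise CombatError("covariate rows must match data rows")
    return covariates, list(names)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch's shrunk location/scale."""
    n = z.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max()
            if np.abs(g_old).max() > 0
            else 0.0,
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def fit_combat(
    data: np.ndarray,
    batch_labels,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> CombatModel:
    """Fit parametric EB ComBat on a subjects x features matrix.

    ``covariates`` are the biological covariates whose effects must be
    preserved (no intercept column; one is implied by the batch one-hot
    block).  Every batch needs at least two subjects.  Deterministic.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise CombatError("data must be 2-D (subjects x features)")
    n, _ = data.shape
    batch_labels = np.asarray(batch_labels)
    if batch_labels.shape[0] != n:
        raise CombatError("batch labels must match data rows")
    batches = sorted(set(batch_labels.tolist()))
    counts = {b: int((batch_labels == b).sum()) for b in batches}
    small = [b for b, c in counts.items() if c < 2]
    if small:
        raise CombatError(f"batches with < 2 subjects: {small}")
    covariates, covariate_names = _check_covariates(covariates, covariate_names, n)

    design = _design(batch_labels, batches, covariates)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        for j in range(len(batches), design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(covariate_names[j - len(batches)])
        raise CombatError(
            f"singular design; collinear covariate columns: {bad or covariate_names}"
        )

    Yt = data.T                               # features x subjects
    B_hat = np.linalg.solve(design.T @ design, design.T @ data)  # params x features
    n_batch = len(batches)
    weights = np.array([counts[b] / n for b in batches])
    grand_mean = weights @ B_hat[:n_batch]
    beta_cov = B_hat[n_batch:]

    fitted = design @ B_hat
    var_pooled = ((data - fitted) ** 2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, np.finfo(float).tiny, var_pooled)

    stand_mean = grand_mean[None, :] + covariates @ beta_cov
    Z = (data - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.empty((n_batch, data.shape[1]))
    delta_hat = np.empty((n_batch, data.shape[1]))
    for i, b in enumerate(batches):
        zb = Z[batch_labels == b]
        gamma_hat[i] = zb.mean(axis=0)
        delta_hat[i] = zb.var(axis=0, ddof=1)
    delta_hat = np.where(delta_hat <= 0, np.finfo(float).tiny, delta_hat)

    if n_batch == 1:
        # One batch: there is no reference to adjust against, so
        # harmonization is the identity transform.
        gamma_star = np.zeros_like(gamma_hat)
        delta_star = np.ones_like(delta_hat)
    elif data.shape[1] >= 2:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, b in enumerate(batches):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1)
            a = _aprior(delta_hat[i])
            bp = _bprior(delta_hat[i])
            zb = Z[batch_labels == b]
            if t2 <= 0 or not np.isfinite(a) or not np.isfinite(bp):
                gamma_star[i], delta_star[i] = gamma_hat[i], delta_hat[i]
            else:
                gamma_star[i], delta_star[i] = _it_sol(
                    zb, gamma_hat[i], delta_hat[i], g_bar, t2, a, bp
                )
    else:
        # EB shrinkage pools across features; with a single feature fall
        # back to the unshrunk per-batch estimates.
        gamma_star, delta_star = gamma_hat, delta_hat
    delta_star = np.where(delta_star <= 0, np.finfo(float).tiny, delta_star)

    del Yt
    return CombatModel(
        batches=batches,
        covariate_names=covariate_names,
        grand_mean=grand_mean,
        beta_cov=beta_cov,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
    )


def apply_combat(
    model: CombatModel,
    data: np.ndarray,
    batch_labels,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Harmonize subjects x features data with a fitted ComBat model.

    Standardizes with the model's pooled parameters, removes the EB batch
    location/scale effects, and restores grand mean plus biological
    covariate effects.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    batch_labels = np.asarray(batch_labels)
    unseen = sorted(set(batch_labels.tolist()) - set(model.batches))
    if unseen:
        raise CombatError(f"unseen batch labels: {unseen}")
    if data.shape[1] != model.var_pooled.shape[0]:
        raise CombatError(
            f"feature count {data.shape[1]} != model {model.var_pooled.shape[0]}"
        )
    covariates, _ = _check_covariates(covariates, model.covariate_names, n)
    if covariates.shape[1] != model.beta_cov.shape[0]:
        raise CombatError("covariate count inconsistent with model")

    stand_mean = model.grand_mean[None, :] + covariates @ model.beta_cov
    Z = (data - stand_mean) / np.sqrt(model.var_pooled)[None, :]
    out = np.empty_like(Z)
    for i, b in enumerate(model.batches):
        idx = batch_labels == b
        if not idx.any():
            continue
        out[idx] = (Z[idx] - model.gamma_star[i][None, :]) / np.sqrt(
            model.delta_star[i]
        )[None, :]
    return out * np.sqrt(model.var_pooled)[None, :] + stand_mean


def harmonize(
    data: np.ndarray,
    batch_labels,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> tuple[np.ndarray, CombatModel]:
    """Convenience fit + apply on the same data."""
    model = fit_combat(data, batch_labels, covariates, covariate_names)
    return apply_combat(model, data, batch_labels, covariates), model
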
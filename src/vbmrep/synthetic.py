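"""Synthetic multi-cohort generator for the replicability pipeline.

Generates subject tables and voxelwise gray-matter images (plus optional
region tables) with the statistical structure the analysis assumes:

* three cohorts of unequal size and age structure;
* right-skewed, inter-correlated CTQ subscales from a latent maltreatment
  severity trait discretized to 25 items;
* strong maltreatment-diagnosis confounding (the default preset is
  calibrated so that the severe-vs-none maltreatment odds ratio for MDD is
  around 18);
* six scanner groups with additive/multiplicative site effects;
* spatially smooth voxel noise (Gaussian-filtered white noise, FWHM
  configurable, 8 mm-like by default);
* optional injected maltreatment effect clusters of specified partial R²
  (negative direction by default: more maltreatment, less gray matter).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from . import ctq
from .datasets import VoxelDataset

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Latent-trait CTQ model: one latent severity factor, subscale loadings,
# item loadings, and right-skewed discretization thresholds (z units).
# Calibrated to coarse features of adult HC/MDD samples: subscale medians
# near the scale minimum, highly inter-correlated subscales, roughly 18%
# 'severe' and 38% 'none to minimal' under the default diagnosis mix.
SUBSCALE_LOADING = 0.80
ITEM_LOADING = 0.85
ITEM_CUTS = (0.65, 1.25, 1.85, 2.45)

#: Latent severity -> MDD log-odds slope calibrated so the severe-vs-none
#: odds ratio for MDD is about 18 at the default diagnosis mix.
DEFAULT_CONFOUNDING_SLOPE = 1.8
#: Severe-CM x MDD odds-ratio magnitude the calibrated preset aims to echo.
TARGET_SEVERE_MDD_OR = 18.45


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class CohortConfig:
    """One cohort's demographic, clinical and scanner structure."""

    name: str
    n_subjects: int
    age_mean: float = 38.0
    age_sd: float = 13.0
    age_bounds: tuple[float, float] = (18.0, 65.0)
    female_frac: float = 0.6
    mdd_frac: float = 0.4
    scanner_groups: tuple[str, ...] = ("scanner_1",)
    scanner_probs: tuple[float, ...] | None = None
    confounding_slope: float = DEFAULT_CONFOUNDING_SLOPE
    med_naive_frac: float = 0.3
    include_items: bool = False
    clinical_scores: bool = True

    def __post_init__(self) -> None:
        for frac_name in ("female_frac", "mdd_frac", "med_naive_frac"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac_name}={v} outside [0, 1]")
        if self.n_subjects < 8:
            raise ConfigError("n_subjects must be at least covariate count + 2")
        if self.mdd_frac == 0.0 and self.med_naive_frac > 0.0:
            raise ConfigError("med_naive_frac > 0 requires mdd_frac > 0")
        if self.scanner_probs is not None and len(self.scanner_probs) != len(
            self.scanner_groups
        ):
            raise ConfigError("scanner_probs length must match scanner_groups")


@dataclass(frozen=True)
class EffectSpec:
    """A spherical maltreatment effect cluster of a target partial R²."""

    predictor: str = "ctq_sum"
    center: tuple[int, int, int] = (8, 8, 8)
    radius: int = 2
    partial_r2: float = 0.1
    direction: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.partial_r2 <= 0.5:
            raise ConfigError("target partial R² must be in [0, 0.5]")
        if self.direction not in (-1, 1):
            raise ConfigError("direction must be -1 or +1")


@dataclass(frozen=True)
class ImageConfig:
    """Voxel grid geometry, covariate/site effect sizes, noise model."""

    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 4.0
    template_amplitude: float = 0.75
    template_floor: float = 0.05
    age_slope: float = -0.0012      # GM density units per year
    sex_offset: float = 0.015       # female minus male
    tiv_reference: float = 1450.0   # ml; images scale with TIV/reference
    site_effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.25          # white-noise sd before smoothing
    fwhm_mm: float = 8.0
    mask_threshold: float = 0.1
    effects: tuple[EffectSpec, ...] = ()

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ConfigError("grid must be 3-D with all dims >= 4")
        if self.fwhm_mm < 0:
            raise ConfigError("FWHM must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise sd must be > 0")
        for eff in self.effects:
            for axis in range(3):
                c = eff.center[axis]
                if c - eff.radius < 0 or c + eff.radius >= self.shape[axis]:
                    raise ConfigError(
                        f"effect cluster at {eff.center} radius {eff.radius} "
                        f"exceeds grid {self.shape}"
                    )


def default_cohorts(scale: float = 1.0) -> list[CohortConfig]:
    """Three-cohort preset emulating the study structure.

    Cohort sizes, age structure, sex mix, diagnosis mix, medication-naive
    fractions and the six scanner groups mirror the study's sample
    composition; ``scale`` shrinks all cohorts proportionally for fast
    test runs.
    """

    def n(x: int) -> int:
        return max(20, int(round(x * scale)))

    return [
        CohortConfig(
            name="MACS",
            n_subjects=n(1752),
            age_mean=35.3,
            age_sd=13.1,
            female_frac=0.647,
            mdd_frac=822 / 1752,
            scanner_groups=("MACS_MS", "MACS_MR_pre", "MACS_MR_post"),
            scanner_probs=(0.45, 0.275, 0.275),
            med_naive_frac=334 / 822,
        ),
        CohortConfig(
            name="MNC",
            n_subjects=n(916),
            age_mean=35.4,
            age_sd=12.5,
            female_frac=0.554,
            mdd_frac=269 / 916,
            scanner_groups=("MNC_pre", "MNC_post"),
            scanner_probs=(0.5, 0.5),
            med_naive_frac=39 / 269,
        ),
        CohortConfig(
            name="BiDirect",
            n_subjects=n(557),
            age_mean=51.8,
            age_sd=7.7,
            female_frac=0.526,
            mdd_frac=236 / 557,
            scanner_groups=("BiDirect",),
            med_naive_frac=34 / 236,
        ),
    ]


def _draw_items(latent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Discretize latent severity into 25 item scores (n x 25)."""
    n = latent.shape[0]
    items = np.empty((n, 25), dtype=int)
    cuts = np.asarray(ITEM_CUTS)
    for k in range(5):
        sub_lat = SUBSCALE_LOADING * latent + np.sqrt(
            1 - SUBSCALE_LOADING**2
        ) * rng.standard_normal(n)
        for j in range(5):
            item_lat = ITEM_LOADING * sub_lat + np.sqrt(
                1 - ITEM_LOADING**2
            ) * rng.standard_normal(n)
            items[:, 5 * k + j] = 1 + (item_lat[:, None] > cuts[None, :]).sum(axis=1)
    return items


def _solve_intercept(latent: np.ndarray, slope: float, target_frac: float) -> float:
    """Bisection for the logistic intercept hitting the diagnosis fraction."""
    if target_frac <= 0.0:
        return -np.inf
    if target_frac >= 1.0:
        return np.inf
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(1.0 / (1.0 + np.exp(-(mid + slope * latent)))))
        if frac < target_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_subjects(cfg: CohortConfig, seed: int) -> pd.DataFrame:
    """Simulate one cohort's subject table; deterministic given the seed.

    Columns: subject_id, cohort, scanner_group, age, sex, TIV, diagnosis,
    med_naive, EA..PN subscale sums, CTQ_SUM, extreme_group, and (when
    enabled) clinical scores; items as ctq_i01..ctq_i25 when requested.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects

    lo = (cfg.age_bounds[0] - cfg.age_mean) / cfg.age_sd
    hi = (cfg.age_bounds[1] - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(
        lo, hi, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng
    )
    female = rng.random(n) < cfg.female_frac
    tiv = np.exp(rng.normal(np.log(1400.0), 0.07, size=n)) * np.where(
        female, 1.0, 1.12
    )

    latent = rng.standard_normal(n)
    items = _draw_items(latent, rng)
    scored = [ctq.score_ctq(row) for row in items]
    subscales = {
        key: np.array([s.subscale_sums[key] for s in scored]) for key in ctq.SUBSCALES
    }
    total = np.array([s.total_sum for s in scored])
    labels = [ctq.assign_extreme_group(s) for s in scored]

    b0 = _solve_intercept(latent, cfg.confounding_slope, cfg.mdd_frac)
    if np.isinf(b0):
        mdd = np.full(n, b0 > 0)
    else:
        p_mdd = 1.0 / (1.0 + np.exp(-(b0 + cfg.confounding_slope * latent)))
        mdd = rng.random(n) < p_mdd
    med_naive = mdd & (rng.random(n) < cfg.med_naive_frac)

    probs = cfg.scanner_probs or tuple(
        1.0 / len(cfg.scanner_groups) for _ in cfg.scanner_groups
    )
    scanner = rng.choice(cfg.scanner_groups, size=n, p=np.asarray(probs) / np.sum(probs))

    table = pd.DataFrame(
        {
            "subject_id": [f"{cfg.name}_{i:05d}" for i in range(n)],
            "cohort": cfg.name,
            "scanner_group": scanner,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "TIV": tiv,
            "diagnosis": np.where(mdd, "MDD", "HC"),
            "med_naive": med_naive,
            **{key: subscales[key] for key in ctq.SUBSCALES},
            "CTQ_SUM": total,
            "extreme_group": labels,
        }
    )
    if cfg.clinical_scores:
        hdrs = np.where(
            mdd,
            np.clip(rng.normal(17.0, 6.0, n) + 1.5 * latent, 0, 52),
            np.clip(rng.normal(2.0, 2.0, n), 0, 52),
        )
        episodes = np.where(
            mdd, 1 + rng.poisson(np.clip(2.0 + 0.8 * latent, 0.1, None)), 0
        )
        table["hdrs"] = np.round(hdrs).astype(int)
        table["n_episodes"] = episodes.astype(int)
    if cfg.include_items:
        for j in range(25):
            table[f"ctq_i{j + 1:02d}"] = items[:, j]
    return table


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size: float) -> float:
    """Gaussian kernel sigma (voxel units) for a FWHM in mm."""
    return fwhm_mm * FWHM_TO_SIGMA / voxel_size


def smoothing_variance_factor(cfg: ImageConfig) -> float:
    """Variance retention factor of smoothing white noise on this grid.

    Computed exactly as the sum of squared kernel weights (impulse
    response of the separable Gaussian filter), so the effective per-voxel
    noise sd is ``noise_sd * sqrt(factor)``.
    """
    sigma = fwhm_to_sigma_voxels(cfg.fwhm_mm, cfg.voxel_size)
    if sigma <= 0:
        return 1.0
    delta = np.zeros(cfg.shape)
    delta[tuple(s // 2 for s in cfg.shape)] = 1.0
    kernel = gaussian_filter(delta, sigma=sigma, mode="constant")
    return float((kernel**2).sum())


def _template(cfg: ImageConfig) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(s, dtype=float) for s in cfg.shape], indexing="ij"
    )
    r2 = sum(
        ((g - (s - 1) / 2.0) / (0.35 * s)) ** 2 for g, s in zip(grids, cfg.shape)
    )
    return cfg.template_floor + cfg.template_amplitude * np.exp(-0.5 * r2)


def _residualize(x: np.ndarray, covars: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(covars, x, rcond=None)
    return x - covars @ beta


def simulate_images(
    table: pd.DataFrame, cfg: ImageConfig, seed: int
) -> VoxelDataset:
    """Simulate gray-matter images for the subjects of ``table``.

    Voxel value = TIV-scaled (template + covariate terms) + effect-cluster
    terms + site additive shift + site-scaled smoothed Gaussian noise.
    The analysis mask keeps voxels whose across-subject mean exceeds the
    absolute threshold (default 0.1).
    """
    from .glm import absolute_threshold_mask  # local import avoids cycle

    if len(table) == 0:
        raise ConfigError("subject table is empty")
    rng = np.random.default_rng(seed)
    n = len(table)
    template = _template(cfg)

    age = table["age"].to_numpy(dtype=float)
    female = (table["sex"] == "female").to_numpy(dtype=float)
    tiv = table["TIV"].to_numpy(dtype=float)

    covar_term = cfg.age_slope * (age - age.mean()) + cfg.sex_offset * female
    tiv_scale = tiv / cfg.tiv_reference

    stack = (
        template[None, :, :, :] + covar_term[:, None, None, None]
    ) * tiv_scale[:, None, None, None]

    # injected effect clusters, slope calibrated against the predictor's
    # covariate-residual variance and the effective (smoothed) noise sd
    if cfg.effects:
        from .models import predictor_values

        covars = np.column_stack([np.ones(n), age, female, tiv])
        sd_eff = cfg.noise_sd * np.sqrt(smoothing_variance_factor(cfg))
        coords = np.indices(cfg.shape)
        for eff in cfg.effects:
            x = np.asarray(predictor_values(table, eff.predictor), dtype=float)
            x_res_sd = _residualize(x, covars).std()
            if x_res_sd <= 0:
                raise ConfigError(
                    f"predictor {eff.predictor!r} has no residual variance"
                )
            r2 = eff.partial_r2
            beta = eff.direction * np.sqrt(r2 / (1.0 - r2)) * sd_eff / x_res_sd
            dist2 = sum(
                (coords[a] - eff.center[a]) ** 2 for a in range(3)
            )
            sphere = dist2 <= eff.radius**2
            stack += (
                beta * (x - x.mean())[:, None, None, None] * sphere[None, :, :, :]
            )

    noise = rng.standard_normal((n,) + cfg.shape) * cfg.noise_sd
    sigma = fwhm_to_sigma_voxels(cfg.fwhm_mm, cfg.voxel_size)
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=(0, sigma, sigma, sigma))

    site_add = np.zeros(n)
    site_mult = np.ones(n)
    if cfg.site_effects:
        groups = table["scanner_group"].to_numpy()
        for g, (add, mult) in cfg.site_effects.items():
            idx = groups == g
            site_add[idx] = add
            site_mult[idx] = mult
    stack += site_add[:, None, None, None] + site_mult[:, None, None, None] * noise

    mask = absolute_threshold_mask(stack, cfg.mask_threshold)
    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    return VoxelDataset(
        data=stack[:, mask],
        mask=mask,
        affine=affine,
        subject_ids=list(table["subject_id"]),
        voxel_size=cfg.voxel_size,
        meta={"seed": seed, "fwhm_mm": cfg.fwhm_mm, "noise_sd": cfg.noise_sd},
    )


REGION_KINDS = ("thickness", "surface", "subcortical_volume")


def simulate_region_table(
    table: pd.DataFrame,
    n_cortical: int = 140,
    n_subcortical: int = 14,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate parcellation endpoints (thickness/surface/subcortical volume).

    Returns ``(regions, meta)``: a subjects x regions table (140 cortical
    split between thickness and surface, 14 subcortical volumes by
    default) and a region metadata table tagging each region's kind.
    Covariate structure is analogous to the voxel generator: age decline,
    sex offset, and TIV scaling for areal/volumetric (not thickness)
    measures.
    """
    if n_cortical < 1 or n_subcortical < 1:
        raise ConfigError("region counts must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(table)
    age = table["age"].to_numpy(dtype=float)
    female = (table["sex"] == "female").to_numpy(dtype=float)
    tiv = table["TIV"].to_numpy(dtype=float)
    tiv_scale = tiv / tiv.mean()

    n_thick = n_cortical // 2
    n_surf = n_cortical - n_thick
    cols: dict[str, np.ndarray] = {}
    meta_rows = []

    def make(kind: str, count: int, base: float, sd: float, scale_tiv: bool):
        for i in range(count):
            name = f"{kind}_{i:03d}"
            vals = base * (1.0 - 0.002 * (age - age.mean())) + 0.01 * base * female
            if scale_tiv:
                vals = vals * tiv_scale
            cols[name] = vals + rng.normal(0.0, sd, n)
            meta_rows.append({"region": name, "kind": kind})

    make("thickness", n_thick, base=2.5, sd=0.15, scale_tiv=False)
    make("surface", n_surf, base=2500.0, sd=250.0, scale_tiv=True)
    make("subcortical_volume", n_subcortical, base=4000.0, sd=400.0, scale_tiv=True)

    regions = pd.DataFrame(cols, index=table.index)
    meta = pd.DataFrame(meta_rows)
    return regions, meta


def simulate_cohorts(
    cohort_cfgs: Sequence[CohortConfig],
    image_cfg: ImageConfig,
    seed: int,
) -> dict[str, tuple[pd.DataFrame, VoxelDataset]]:
    """Simulate subject tables and images for several cohorts.

    Per-cohort seeds are derived deterministically from ``seed``.
    """
    out: dict[str, tuple[pd.DataFrame, VoxelDataset]] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(cohort_cfgs))
    for i, cfg in enumerate(cohort_cfgs):
        s_table = int(children[2 * i].generate_state(1)[0] % (2**31))
        s_img = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        tab = simulate_subjects(cfg, s_table)
        img = simulate_images(tab, image_cfg, s_img)
        out[cfg.name] = (tab, img)
    return out


def scaled_effect(cfg: ImageConfig, partial_r2: float, **kwargs) -> ImageConfig:
    """Convenience: a copy of ``cfg`` with one centered effect cluster."""
    center = tuple(s // 2 for s in cfg.shape)
    eff = EffectSpec(center=center, partial_r2=partial_r2, **kwargs)
    return replace(cfg, effects=(eff,))
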
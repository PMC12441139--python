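"""The 18-model analysis grid and grid execution across cohorts.

The grid varies the maltreatment operationalization (CTQ total, abuse and
neglect composites, the five subscales, severe-vs-none extreme groups, and
a CTQ-by-age interaction), whether lifetime MDD diagnosis is controlled,
and the subsample (full HC+MDD, HC only, MDD only, medication-naive MDD).
Age, sex and TIV are covariates in every model.  Main effects are tested
one-sided in the negative direction (more maltreatment, lower gray
matter); interactions two-sided.  Every model can additionally be run
stratified by sex (the sex covariate is then dropped) and over regional
endpoints (TIV dropped for cortical thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import VoxelDataset, common_mask, subset_to_mask
from .glm import (
    DesignMatrix,
    SignificanceMap,
    StatMap,
    fit_glm_voxelwise,
    threshold_map,
)

PREDICTOR_KINDS = (
    "ctq_sum",
    "abuse",
    "neglect",
    "ea",
    "pa",
    "sa",
    "en",
    "pn",
    "extreme_group",
    "ctq_sum_x_age",
)
SUBSAMPLES = ("all", "HC", "MDD", "MDD_med_naive")


class ModelSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One analysis of the grid (predictor, covariate set, subsample)."""

    model_id: int
    predictor: str
    control_diagnosis: bool
    subsample: str = "all"
    sidedness: str = "one_sided_negative"
    sex_stratum: str = "all"
    endpoint: str = "voxel"

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTOR_KINDS:
            raise ModelSpecError(f"unknown predictor {self.predictor!r}")
        if self.subsample not in SUBSAMPLES:
            raise ModelSpecError(f"unknown subsample {self.subsample!r}")
        if self.predictor == "ctq_sum_x_age" and self.sidedness != "two_sided":
            raise ModelSpecError("interaction models must be two-sided")
        if self.control_diagnosis and self.subsample != "all":
            raise ModelSpecError(
                "diagnosis control is only meaningful in the full (HC+MDD) sample"
            )
        if self.sex_stratum not in ("all", "female", "male"):
            raise ModelSpecError(f"unknown sex stratum {self.sex_stratum!r}")

    def stratified(self, sex: str) -> "ModelSpec":
        return replace(self, sex_stratum=sex)

    def with_endpoint(self, endpoint: str) -> "ModelSpec":
        return replace(self, endpoint=endpoint)


def enumerate_models() -> list[ModelSpec]:
    """The 18 models of the grid, in canonical order."""
    m = ModelSpec
    return [
        m(1, "ctq_sum", True, "all"),
        m(2, "ctq_sum", False, "all"),
        m(3, "ctq_sum", False, "HC"),
        m(4, "ctq_sum", False, "MDD"),
        m(5, "abuse", True, "all"),
        m(6, "neglect", True, "all"),
        m(7, "ea", True, "all"),
        m(8, "pa", True, "all"),
        m(9, "sa", True, "all"),
        m(10, "en", True, "all"),
        m(11, "pn", True, "all"),
        m(12, "extreme_group", True, "all"),
        m(13, "extreme_group", False, "all"),
        m(14, "extreme_group", False, "HC"),
        m(15, "extreme_group", False, "MDD"),
        m(16, "ctq_sum", False, "MDD_med_naive"),
        m(17, "ctq_sum_x_age", False, "HC", "two_sided"),
        m(18, "ctq_sum_x_age", False, "MDD", "two_sided"),
    ]


_SUBSCALE_COLUMN = {"ea": "EA", "pa": "PA", "sa": "SA", "en": "EN", "pn": "PN"}


def predictor_values(table: pd.DataFrame, kind: str) -> np.ndarray:
    """Numeric predictor column for a maltreatment operationalization.

    Extreme groups are coded severe = 1, none_minimal = 0 (intermediate
    rows must have been filtered out); the interaction predictor is the
    product of centered CTQ sum and centered age.
    """
    kind = kind.lower()
    if kind == "ctq_sum":
        return table["CTQ_SUM"].to_numpy(dtype=float)
    if kind == "abuse":
        return (table["EA"] + table["PA"] + table["SA"]).to_numpy(dtype=float)
    if kind == "neglect":
        return (table["EN"] + table["PN"]).to_numpy(dtype=float)
    if kind in _SUBSCALE_COLUMN:
        return table[_SUBSCALE_COLUMN[kind]].to_numpy(dtype=float)
    if kind == "extreme_group":
        labels = table["extreme_group"]
        if (labels == "intermediate").any():
            raise ModelSpecError(
                "intermediate subjects must be excluded before coding extreme groups"
            )
        return (labels == "severe").to_numpy(dtype=float)
    if kind == "ctq_sum_x_age":
        ctq_c = table["CTQ_SUM"].to_numpy(dtype=float)
        age_c = table["age"].to_numpy(dtype=float)
        return (ctq_c - ctq_c.mean()) * (age_c - age_c.mean())
    raise ModelSpecError(f"unknown predictor kind {kind!r}")


def filter_subsample(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Restrict a subject table to a model's subsample and stratum."""
    out = table
    if spec.subsample == "HC":
        out = out[out["diagnosis"] == "HC"]
    elif spec.subsample == "MDD":
        out = out[out["diagnosis"] == "MDD"]
    elif spec.subsample == "MDD_med_naive":
        if "med_naive" not in out.columns:
            raise ModelSpecError("table lacks a med_naive column")
        out = out[(out["diagnosis"] == "MDD") & out["med_naive"].astype(bool)]
    if spec.predictor == "extreme_group":
        out = out[out["extreme_group"].isin(["severe", "none_minimal"])]
    if spec.sex_stratum != "all":
        out = out[out["sex"] == spec.sex_stratum]
    if len(out) == 0:
        raise ModelSpecError(f"model {spec.model_id}: empty subsample")
    return out


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Design matrix for one model on an already-filtered subject table.

    Columns: intercept, tested predictor (for interactions: centered main
    effects plus their product, the product being tested), then covariates
    age, sex (unless sex-stratified), TIV (unless a thickness endpoint),
    and diagnosis when the model controls for it.  Continuous variables
    enter uncentered except where the interaction requires centering.
    """
    n = len(table)
    age = table["age"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    if spec.predictor == "ctq_sum_x_age":
        ctq_c = table["CTQ_SUM"].to_numpy(dtype=float)
        ctq_c = ctq_c - ctq_c.mean()
        age_c = age - age.mean()
        cols += [ctq_c, age_c, ctq_c * age_c]
        names += ["CTQ_SUM_c", "age_c", "CTQ_SUM_x_age"]
        test_idx = 3
    else:
        cols.append(predictor_values(table, spec.predictor))
        names.append(spec.predictor)
        test_idx = 1
        cols.append(age)
        names.append("age")

    if spec.sex_stratum == "all":
        cols.append((table["sex"] == "female").to_numpy(dtype=float))
        names.append("sex_female")
    if spec.endpoint != "thickness":
        cols.append(table["TIV"].to_numpy(dtype=float))
        names.append("TIV")
    if spec.control_diagnosis:
        cols.append((table["diagnosis"] == "MDD").to_numpy(dtype=float))
        names.append("diagnosis_MDD")

    return DesignMatrix(X=np.column_stack(cols), names=names, test_idx=test_idx)


@dataclass
class GridResult:
    """Fitted maps per (model, cohort-or-pooled, threshold) cell."""

    stat_maps: dict = field(default_factory=dict)
    sig_maps: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def cell(self, model_id: int, cohort: str, threshold: str) -> SignificanceMap:
        return self.sig_maps[(model_id, cohort, threshold)]


def _fit_cell(
    table: pd.DataFrame, Y: np.ndarray, spec: ModelSpec
) -> tuple[StatMap, DesignMatrix, np.ndarray]:
    sub = filter_subsample(table.reset_index(drop=True), spec)
    design = build_design(sub, spec)
    Ysub = Y[sub.index.to_numpy()]
    smap = fit_glm_voxelwise(Ysub, design, spec.sidedness)
    smap.model_id = spec.model_id
    return smap, design, Ysub


def run_grid(
    cohorts: dict[str, tuple[pd.DataFrame, VoxelDataset]],
    specs: list[ModelSpec] | None = None,
    alphas: tuple[float, ...] = (0.001, 0.01),
    pooled: bool = True,
    fwe_method: str = "maxT_permutation",
    fwe_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    keep_stat_maps: bool = True,
) -> GridResult:
    """Fit the model grid cohort-wise (uncorrected thresholds) and pooled (FWE).

    Datasets must share the grid; columns are aligned to the intersection
    of cohort masks.  The pooled analysis concatenates the (ComBat-
    harmonized) cohorts and applies voxel-level FWE control; per-cohort
    maps are thresholded at each uncorrected ``alpha`` for the
    replicability stage.  Cells that cannot be fitted (e.g. a missing
    column) are recorded as failures and the run continues.
    """
    specs = specs if specs is not None else enumerate_models()
    if fwe_method == "maxT_permutation" and seed is None:
        raise ValueError("maxT FWE requires a seed")

    datasets = [cohorts[name][1] for name in cohorts]
    mask = common_mask(datasets)
    aligned = {
        name: (cohorts[name][0], subset_to_mask(cohorts[name][1], mask))
        for name in cohorts
    }
    result = GridResult(
        mask=mask,
        metadata={
            "alphas": list(alphas),
            "fwe_method": fwe_method,
            "fwe_alpha": fwe_alpha,
            "n_perm": n_perm,
            "seed": seed,
        },
    )

    for spec in specs:
        for name, (table, dataset) in aligned.items():
            try:
                smap, design, Ysub = _fit_cell(table, dataset.data, spec)
                smap.cohort = name
                if keep_stat_maps:
                    result.stat_maps[(spec.model_id, name)] = smap
                for alpha in alphas:
                    sig = threshold_map(smap, "uncorrected", alpha)
                    result.sig_maps[(spec.model_id, name, f"unc_{alpha:g}")] = sig
            except Exception as exc:  # per-cell failure, run continues
                result.failures[(spec.model_id, name)] = str(exc)

        if pooled:
            try:
                pooled_table = pd.concat(
                    [aligned[name][0] for name in aligned], ignore_index=True
                )
                pooled_Y = np.vstack([aligned[name][1].data for name in aligned])
                smap, design, Ysub = _fit_cell(pooled_table, pooled_Y, spec)
                smap.cohort = "pooled"
                if keep_stat_maps:
                    result.stat_maps[(spec.model_id, "pooled")] = smap
                sig = threshold_map(
                    smap,
                    fwe_method,
                    fwe_alpha,
                    Y=Ysub,
                    design=design,
                    n_perm=n_perm,
                    seed=seed,
                )
                result.sig_maps[(spec.model_id, "pooled", "fwe")] = sig
            except Exception as exc:
                result.failures[(spec.model_id, "pooled")] = str(exc)

    return result


def pooled_summary_table(result: GridResult) -> pd.DataFrame:
    """Pooled-analysis summary: significant voxel count and partial R² range."""
    rows = []
    for (model_id, cohort, threshold), sig in sorted(
        result.sig_maps.items(), key=lambda kv: str(kv[0])
    ):
        if cohort != "pooled":
            continue
        smap = result.stat_maps.get((model_id, "pooled"))
        k = sig.n_significant
        if smap is not None and k > 0:
            pr2 = smap.partial_r2[sig.values]
            lo, hi = float(np.nanmin(pr2)), float(np.nanmax(pr2))
        else:
            lo = hi = np.nan
        rows.append(
            {
                "model": model_id,
                "threshold": threshold,
                "k_significant": k,
                "partial_r2_min": lo,
                "partial_r2_max": hi,
            }
        )
    return pd.DataFrame(rows)
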
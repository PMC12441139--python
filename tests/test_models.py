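"""The 18-model grid: spec encoding, subsampling, designs, execution."""

import numpy as np
import pandas as pd
import pytest

from vbmrep import glm
from vbmrep import models as mg
from vbmrep import synthetic as syn

# frozen snapshot of the grid definition
GRID_SNAPSHOT = [
    (1, "ctq_sum", True, "all", "one_sided_negative"),
    (2, "ctq_sum", False, "all", "one_sided_negative"),
    (3, "ctq_sum", False, "HC", "one_sided_negative"),
    (4, "ctq_sum", False, "MDD", "one_sided_negative"),
    (5, "abuse", True, "all", "one_sided_negative"),
    (6, "neglect", True, "all", "one_sided_negative"),
    (7, "ea", True, "all", "one_sided_negative"),
    (8, "pa", True, "all", "one_sided_negative"),
    (9, "sa", True, "all", "one_sided_negative"),
    (10, "en", True, "all", "one_sided_negative"),
    (11, "pn", True, "all", "one_sided_negative"),
    (12, "extreme_group", True, "all", "one_sided_negative"),
    (13, "extreme_group", False, "all", "one_sided_negative"),
    (14, "extreme_group", False, "HC", "one_sided_negative"),
    (15, "extreme_group", False, "MDD", "one_sided_negative"),
    (16, "ctq_sum", False, "MDD_med_naive", "one_sided_negative"),
    (17, "ctq_sum_x_age", False, "HC", "two_sided"),
    (18, "ctq_sum_x_age", False, "MDD", "two_sided"),
]


class TestEnumeration:
    def test_grid_has_18_models_matching_snapshot(self):
        specs = mg.enumerate_models()
        assert len(specs) == 18
        got = [
            (s.model_id, s.predictor, s.control_diagnosis, s.subsample, s.sidedness)
            for s in specs
        ]
        assert got == GRID_SNAPSHOT

    def test_model_13_and_16_fields(self):
        by_id = {s.model_id: s for s in mg.enumerate_models()}
        m13 = by_id[13]
        assert m13.predictor == "extreme_group"
        assert not m13.control_diagnosis
        assert m13.subsample == "all"
        assert by_id[16].subsample == "MDD_med_naive"

    def test_interaction_must_be_two_sided(self):
        with pytest.raises(mg.ModelSpecError):
            mg.ModelSpec(99, "ctq_sum_x_age", False, "HC", "one_sided_negative")

    def test_diagnosis_control_only_in_full_sample(self):
        with pytest.raises(mg.ModelSpecError):
            mg.ModelSpec(99, "ctq_sum", True, "HC")


def _toy_table():
    rng = np.random.default_rng(1)
    rows = []
    labels = ["none_minimal"] * 4 + ["severe"] * 3 + ["intermediate"] * 3
    for i in range(10):
        rows.append(
            {
                "subject_id": f"s{i}",
                "cohort": "toy",
                "scanner_group": "g",
                "age": float(rng.integers(20, 60)),
                "sex": "female" if i < 6 else "male",
                "TIV": float(rng.normal(1450, 80)),
                "diagnosis": "HC" if i < 5 else "MDD",
                "med_naive": i in (5, 6),
                "EA": 5, "PA": 5, "SA": 5, "EN": 5, "PN": 5,
                "CTQ_SUM": int(rng.integers(25, 80)),
                "extreme_group": labels[i],
            }
        )
    return pd.DataFrame(rows)


class TestFiltering:
    def test_hc_subsample(self):
        t = pd.concat([_toy_table()] * 2, ignore_index=True)
        t.loc[10:, "diagnosis"] = "MDD"
        spec = mg.ModelSpec(3, "ctq_sum", False, "HC")
        out = mg.filter_subsample(t, spec)
        assert len(out) == 5 and (out["diagnosis"] == "HC").all()

    def test_extreme_groups_drop_intermediate(self):
        spec = mg.ModelSpec(13, "extreme_group", False, "all")
        out = mg.filter_subsample(_toy_table(), spec)
        assert len(out) == 7
        assert not (out["extreme_group"] == "intermediate").any()

    def test_female_stratum(self):
        spec = mg.ModelSpec(2, "ctq_sum", False, "all").stratified("female")
        out = mg.filter_subsample(_toy_table(), spec)
        assert len(out) == 6 and (out["sex"] == "female").all()

    def test_med_naive_subsample(self):
        spec = mg.ModelSpec(16, "ctq_sum", False, "MDD_med_naive")
        out = mg.filter_subsample(_toy_table(), spec)
        assert len(out) == 2

    def test_empty_subsample_raises_with_model_id(self):
        t = _toy_table()
        t["diagnosis"] = "HC"
        spec = mg.ModelSpec(4, "ctq_sum", False, "MDD")
        with pytest.raises(mg.ModelSpecError, match="model 4"):
            mg.filter_subsample(t, spec)


class TestDesigns:
    def test_model_1_columns(self):
        d = mg.build_design(_toy_table(), mg.ModelSpec(1, "ctq_sum", True))
        assert d.names == [
            "intercept", "ctq_sum", "age", "sex_female", "TIV", "diagnosis_MDD",
        ]
        assert d.test_idx == 1

    def test_model_2_drops_only_diagnosis(self):
        t = _toy_table()
        d1 = mg.build_design(t, mg.ModelSpec(1, "ctq_sum", True))
        d2 = mg.build_design(t, mg.ModelSpec(2, "ctq_sum", False))
        assert d1.names[:-1] == d2.names
        assert np.allclose(d1.X[:, :-1], d2.X)

    def test_model_17_interaction_design(self):
        t = _toy_table()
        t["diagnosis"] = "HC"
        spec = mg.ModelSpec(17, "ctq_sum_x_age", False, "HC", "two_sided")
        d = mg.build_design(t, spec)
        assert d.names == [
            "intercept", "CTQ_SUM_c", "age_c", "CTQ_SUM_x_age", "sex_female", "TIV",
        ]
        assert d.test_idx == 3
        # interaction column is the product of the centered main effects
        assert np.allclose(d.X[:, 3], d.X[:, 1] * d.X[:, 2])

    def test_sex_stratified_design_has_no_sex_column(self):
        spec = mg.ModelSpec(2, "ctq_sum", False).stratified("female")
        sub = mg.filter_subsample(_toy_table(), spec)
        d = mg.build_design(sub, spec)
        assert "sex_female" not in d.names

    def test_single_sex_with_sex_covariate_is_rank_deficient(self):
        t = _toy_table()
        t["sex"] = "female"
        with pytest.raises(glm.DesignError, match="sex-stratified"):
            mg.build_design(t, mg.ModelSpec(2, "ctq_sum", False))

    def test_thickness_endpoint_drops_tiv(self):
        spec = mg.ModelSpec(2, "ctq_sum", False).with_endpoint("thickness")
        d = mg.build_design(_toy_table(), spec)
        assert "TIV" not in d.names

    def test_extreme_group_coding(self):
        spec = mg.ModelSpec(13, "extreme_group", False)
        sub = mg.filter_subsample(_toy_table(), spec)
        x = mg.predictor_values(sub, "extreme_group")
        assert set(x) == {0.0, 1.0}
        assert x.sum() == 3


@pytest.fixture(scope="module")
def small_grid():
    cfgs = [
        syn.CohortConfig(name=n, n_subjects=100, mdd_frac=0.5)
        for n in ("A", "B", "C")
    ]
    icfg = syn.ImageConfig(shape=(8, 8, 8), fwhm_mm=4.0)
    cohorts = syn.simulate_cohorts(cfgs, icfg, seed=77)
    specs = [s for s in mg.enumerate_models() if s.model_id in (1, 2)]
    result = mg.run_grid(
        cohorts,
        specs,
        alphas=(0.001, 0.01),
        pooled=True,
        fwe_method="bonferroni",
    )
    return result


class TestRunGrid:
    def test_bookkeeping_counts(self, small_grid):
        cohort_cells = [
            k for k in small_grid.sig_maps if k[1] != "pooled"
        ]
        pooled_cells = [k for k in small_grid.sig_maps if k[1] == "pooled"]
        assert len(cohort_cells) == 3 * 2 * 2  # cohorts x models x alphas
        assert len(pooled_cells) == 2
        assert not small_grid.failures

    def test_maps_share_common_mask(self, small_grid):
        sizes = {v.values.size for v in small_grid.sig_maps.values()}
        assert sizes == {int(small_grid.mask.sum())}

    def test_missing_column_recorded_as_failure(self):
        cfgs = [syn.CohortConfig(name="A", n_subjects=60, mdd_frac=0.5)]
        cohorts = syn.simulate_cohorts(cfgs, syn.ImageConfig(shape=(6, 6, 6)), 5)
        table, ds = cohorts["A"]
        table = table.drop(columns=["med_naive"])
        specs = [s for s in mg.enumerate_models() if s.model_id == 16]
        result = mg.run_grid(
            {"A": (table, ds)}, specs, pooled=False, fwe_method="bonferroni"
        )
        assert (16, "A") in result.failures
        assert "med_naive" in result.failures[(16, "A")]

    def test_pooled_summary_table_layout(self, small_grid):
        out = mg.pooled_summary_table(small_grid)
        assert set(out["model"]) == {1, 2}
        assert (out["k_significant"] >= 0).all()
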
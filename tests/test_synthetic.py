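"""Synthetic cohort generator: determinism, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest

from vbmrep import glm
from vbmrep import models as mg
from vbmrep import synthetic as syn


def _odds_ratio(table: pd.DataFrame) -> float:
    sev = table["extreme_group"] == "severe"
    none = table["extreme_group"] == "none_minimal"
    mdd = table["diagnosis"] == "MDD"
    a = (sev & ~mdd).sum()
    b = (sev & mdd).sum()
    c = (none & ~mdd).sum()
    d = (none & mdd).sum()
    return (b * c) / (a * d)


class TestSubjects:
    def test_same_seed_identical(self):
        cfg = syn.CohortConfig(name="x", n_subjects=150)
        t1 = syn.simulate_subjects(cfg, 42)
        t2 = syn.simulate_subjects(cfg, 42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_confounding_gives_unit_odds_ratio(self):
        cfg = syn.CohortConfig(
            name="x", n_subjects=20_000, mdd_frac=0.4, confounding_slope=0.0
        )
        table = syn.simulate_subjects(cfg, 5)
        log_or = np.log(_odds_ratio(table))
        # Monte-Carlo error: ~4 sd of the log-OR at these cell counts
        assert abs(log_or) < 4 * 0.07

    def test_calibrated_confounding_hits_target_or(self):
        cfg = syn.CohortConfig(name="x", n_subjects=20_000, mdd_frac=1327 / 3225)
        table = syn.simulate_subjects(cfg, 6)
        orr = _odds_ratio(table)
        target = syn.TARGET_SEVERE_MDD_OR
        assert 0.75 * target <= orr <= 1.25 * target

    def test_ctq_subscales_right_skewed_and_intercorrelated(self):
        cfg = syn.CohortConfig(name="x", n_subjects=5000)
        table = syn.simulate_subjects(cfg, 8)
        for col in ("EA", "PA", "SA", "EN", "PN"):
            assert table[col].median() <= 9  # mass near the scale minimum
            assert table[col].skew() > 0.5
        corr = table[["EA", "PA", "SA", "EN", "PN"]].corr(method="spearman")
        off = corr.to_numpy()[np.triu_indices(5, 1)]
        assert (off > 0.3).all()

    def test_age_respects_bounds_and_cohort_structure(self):
        for cfg in syn.default_cohorts(scale=0.1):
            t = syn.simulate_subjects(cfg, 3)
            assert t["age"].between(18, 65).all()
            assert set(t["scanner_group"]) <= set(cfg.scanner_groups)
        names = [c.name for c in syn.default_cohorts()]
        assert names == ["MACS", "MNC", "BiDirect"]
        groups = [g for c in syn.default_cohorts() for g in c.scanner_groups]
        assert len(groups) == 6

    def test_infeasible_configs_rejected(self):
        with pytest.raises(syn.ConfigError):
            syn.CohortConfig(name="x", n_subjects=100, mdd_frac=0.0,
                             med_naive_frac=0.5)
        with pytest.raises(syn.ConfigError):
            syn.CohortConfig(name="x", n_subjects=100, female_frac=1.5)
        with pytest.raises(syn.ConfigError):
            syn.CohortConfig(name="x", n_subjects=4)


class TestImages:
    def test_degenerate_noise_reproduces_signal_exactly(self):
        cfg = syn.CohortConfig(name="x", n_subjects=30)
        table = syn.simulate_subjects(cfg, 1)
        icfg = syn.ImageConfig(shape=(6, 6, 6), noise_sd=1e-12, fwhm_mm=0.0)
        ds = syn.simulate_images(table, icfg, 2)
        age = table["age"].to_numpy()
        female = (table["sex"] == "female").to_numpy(float)
        tiv = table["TIV"].to_numpy()
        template = syn._template(icfg)
        expected = (
            template[None]
            + (icfg.age_slope * (age - age.mean()) + icfg.sex_offset * female)[
                :, None, None, None
            ]
        ) * (tiv / icfg.tiv_reference)[:, None, None, None]
        assert np.abs(ds.to_4d().transpose(3, 0, 1, 2) - expected * ds.mask).max() < 1e-8

    def test_site_shift_recovered_by_group_means(self):
        cfg = syn.CohortConfig(
            name="x",
            n_subjects=2000,
            scanner_groups=("g1", "g2"),
        )
        table = syn.simulate_subjects(cfg, 4)
        delta = 0.3
        icfg = syn.ImageConfig(
            shape=(6, 6, 6), site_effects={"g2": (delta, 1.0)}, fwhm_mm=0.0
        )
        ds = syn.simulate_images(table, icfg, 5)
        g = table["scanner_group"].to_numpy()
        diff = ds.data[g == "g2"].mean() - ds.data[g == "g1"].mean()
        assert diff == pytest.approx(delta, abs=0.02)

    def test_injected_cluster_partial_r2_calibrated(self):
        # average over seeds: the injected effect size is recovered by refit
        target = 0.1
        vals = []
        for seed in range(5):
            cfg = syn.CohortConfig(name="x", n_subjects=500)
            table = syn.simulate_subjects(cfg, 50 + seed)
            icfg = syn.scaled_effect(
                syn.ImageConfig(shape=(12, 12, 12)), target
            )
            ds = syn.simulate_images(table, icfg, 60 + seed)
            spec = mg.enumerate_models()[1]  # CTQ sum, no diagnosis control
            sub = mg.filter_subsample(table.reset_index(drop=True), spec)
            design = mg.build_design(sub, spec)
            smap = glm.fit_glm_voxelwise(
                ds.data[sub.index.to_numpy()], design, spec.sidedness
            )
            coords = ds.voxel_coords()
            center = np.array(icfg.effects[0].center)
            ci = int(np.where((coords == center).all(axis=1))[0][0])
            vals.append(smap.partial_r2[ci])
        assert abs(np.mean(vals) - target) < 0.03

    def test_smoothed_noise_variance_matches_kernel_factor(self):
        icfg = syn.ImageConfig(shape=(16, 16, 16), fwhm_mm=8.0, noise_sd=1.0)
        factor = syn.smoothing_variance_factor(icfg)
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        sigma = syn.fwhm_to_sigma_voxels(icfg.fwhm_mm, icfg.voxel_size)
        noise = gaussian_filter(
            rng.standard_normal((200,) + icfg.shape), sigma=(0, sigma, sigma, sigma)
        )
        interior = noise[:, 4:-4, 4:-4, 4:-4]
        assert interior.var() == pytest.approx(factor, rel=0.05)

    def test_effect_outside_grid_rejected(self):
        with pytest.raises(syn.ConfigError, match="exceeds grid"):
            syn.ImageConfig(
                shape=(8, 8, 8),
                effects=(syn.EffectSpec(center=(7, 7, 7), radius=2),),
            )

    def test_mask_and_order_invariants(self, small_cohort_table, small_dataset):
        assert small_dataset.n_subjects == len(small_cohort_table)
        assert small_dataset.subject_ids == list(small_cohort_table["subject_id"])
        assert small_dataset.data.shape[1] == small_dataset.mask.sum()

    def test_cluster_recovery_rate(self):
        """An injected cluster (partial R² .05) is found at p<.001 nearly always."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = syn.CohortConfig(name="x", n_subjects=500)
            table = syn.simulate_subjects(cfg, 1000 + seed)
            icfg = syn.scaled_effect(syn.ImageConfig(shape=(10, 10, 10)), 0.05)
            ds = syn.simulate_images(table, icfg, 2000 + seed)
            spec = mg.enumerate_models()[1]
            sub = mg.filter_subsample(table.reset_index(drop=True), spec)
            design = mg.build_design(sub, spec)
            smap = glm.fit_glm_voxelwise(
                ds.data[sub.index.to_numpy()], design, spec.sidedness
            )
            coords = ds.voxel_coords()
            center = np.array(icfg.effects[0].center)
            peak = coords[int(np.nanargmin(smap.t))]
            in_radius = np.sum((peak - center) ** 2) <= icfg.effects[0].radius ** 2
            ci = int(np.where((coords == center).all(axis=1))[0][0])
            if in_radius and smap.beta[ci] < 0 and smap.p[ci] < 0.001:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestRegions:
    def test_region_counts_and_tags(self, small_cohort_table):
        regions, meta = syn.simulate_region_table(small_cohort_table, seed=3)
        assert regions.shape == (len(small_cohort_table), 154)
        assert meta["kind"].value_counts().to_dict() == {
            "thickness": 70,
            "surface": 70,
            "subcortical_volume": 14,
        }

    def test_same_seed_identical(self, small_cohort_table):
        r1, _ = syn.simulate_region_table(small_cohort_table, seed=9)
        r2, _ = syn.simulate_region_table(small_cohort_table, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_maltreatment_t_statistics_are_central(self):
        """With no maltreatment effect, regional t stats follow a central t."""
        from scipy import stats

        tvals = []
        spec = mg.enumerate_models()[1]
        for seed in range(15):
            cfg = syn.CohortConfig(name="x", n_subjects=80)
            table = syn.simulate_subjects(cfg, 300 + seed)
            regions, _ = syn.simulate_region_table(
                table, n_cortical=20, n_subcortical=4, seed=400 + seed
            )
            sub = mg.filter_subsample(table.reset_index(drop=True), spec)
            design = mg.build_design(sub, spec)
            smap = glm.fit_glm_voxelwise(
                regions.to_numpy()[sub.index.to_numpy()], design, spec.sidedness
            )
            tvals.append(smap.t)
        df = 80 - 5
        ks = stats.kstest(np.concatenate(tvals), stats.t(df).cdf)
        assert ks.pvalue > 0.01
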
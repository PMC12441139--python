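import numpy as np
import pandas as pd
import pytest

from vbmrep import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort_table() -> pd.DataFrame:
    cfg = syn.CohortConfig(name="demo", n_subjects=120, mdd_frac=0.5)
    return syn.simulate_subjects(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_image_cfg() -> syn.ImageConfig:
    return syn.ImageConfig(shape=(8, 8, 8), fwhm_mm=4.0, noise_sd=0.2)


@pytest.fixture(scope="session")
def small_dataset(small_cohort_table, tiny_image_cfg):
    return syn.simulate_images(small_cohort_table, tiny_image_cfg, seed=9)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
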
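import numpy as np
import pytest

import glycovar as gv


@pytest.fixture(scope="session")
def tf_annotation():
    return gv.default_tf_annotation()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest Korcula-style cohort shared by read-only tests."""
    cfg = gv.korcula_config(n_samples=300)
    samples, table, truth = gv.generate_cohort(cfg, seed=42)
    return cfg, samples, table, truth


@pytest.fixture(scope="session")
def identity_cal():
    return gv.fit_gu_calibration(gv.chromatography.identity_ladder(25))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
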
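import numpy as np
import pytest

from puprev import ClassifierConfig, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def fast_clf():
    """Reduced classifier profile for CI-speed tests."""
    return ClassifierConfig.test_profile(v_folds=3, n_estimators=30, max_depth=3)


@pytest.fixture(scope="session")
def scar_cohort():
    """Small SCAR cohort with ~20% positives among the unlabeled records."""
    cfg = SyntheticConfig(
        n_records=4000,
        n_covariates=120,
        true_alpha=1 / 3,
        coded_fraction=0.5,
        n_subtypes=1,
        n_informative=30,
        baseline_rate=0.02,
        lift=25,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def snar_cohort():
    """Two-subtype SNAR cohort, labeling propensities proportional to (0.9, 0.05)."""
    cfg = SyntheticConfig(
        n_records=8000,
        n_covariates=200,
        true_alpha=1 / 3,
        coded_fraction=0.5,
        n_subtypes=2,
        label_propensities=(0.9, 0.05),
        n_informative=50,
        baseline_rate=0.02,
        lift=25,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
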
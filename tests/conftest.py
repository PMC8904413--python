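import numpy as np
import pytest

from connectogat import (
    GATConfig,
    RunConfig,
    SplitSpec,
    SyntheticConfig,
    TrainConfig,
    generate_cohort,
    generate_worked_micro,
)
from connectogat.pipeline import build_samples, preprocess_cohort


@pytest.fixture(scope="session")
def micro_cohort():
    cohort, notes = generate_worked_micro(seed=7)
    return cohort, notes


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-scale planted-effect cohort shared by training-level tests."""
    cfg = SyntheticConfig(
        n_patients=14,
        n_controls=10,
        n_nodes=16,
        affected_nodes=(0, 5, 9),
        sc_effect=0.6,
        fc_effect=0.4,
        morph_effect=0.3,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_run_config():
    return RunConfig(
        model=GATConfig(hidden=4, heads1=3, out_features=4, readout_k=6,
                        mlp_hidden=(16, 8), seed=42),
        train=TrainConfig(epochs=30, early_stopping_patience=10, seed=42),
        split=SplitSpec(test_fraction=0.15, val_fraction_of_remainder=0.25,
                        folds=4, seed=42),
        smote=True,
        cv_folds=4,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_samples(small_cohort, small_run_config):
    """Preprocessed, feature-extracted (unnormalized) samples at small scale."""
    pre = preprocess_cohort(small_cohort, small_run_config)
    return build_samples(pre, small_run_config)
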
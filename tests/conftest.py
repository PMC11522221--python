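import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from skelseg import (
    NormalizationMode,
    PhantomSpec,
    PreprocessConfig,
    build_test_dataset,
    build_training_dataset,
    generate_phantom,
    phantom_cohort,
    run_preprocess,
    split_cohort,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic 10-slice phantom with an accessory on slice 1."""
    spec = PhantomSpec(seed=3, accessory_slices=(1,))
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Five randomized phantom patients with skeleton ground truth."""
    return phantom_cohort(5, seed=42)


@pytest.fixture(scope="session")
def training_material():
    """A preprocessed 24-patient phantom cohort split into train/test datasets.

    Scaled-down study conditions: >=200 training slices at 64x64 across five
    sets (Experiment A normalization) and >=50 unshuffled held-out slices.
    """
    cohort = phantom_cohort(27, seed=11, slice_range=(10, 14))
    train_p, test_p = split_cohort(cohort, 0.85, seed=1)
    cfg = PreprocessConfig(normalization_mode=NormalizationMode.A_INTERPATIENT_INTRASET)
    prep_train = [(run_preprocess(ct, cfg), mask) for ct, mask in train_p]
    prep_test = [(run_preprocess(ct, cfg), mask) for ct, mask in test_p]
    train = build_training_dataset(prep_train, seed=2)
    test = build_test_dataset(prep_test)
    truth = np.concatenate([out for _, out in test.sets], axis=0)
    return {"train": train, "test": test, "truth": truth}
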
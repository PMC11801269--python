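import numpy as np
import pytest

from flexfuse import SimConfig, TrainConfig, generate_cohort, train


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tabular_cohort():
    """Small three-table cohort with planted clinical+proteomic signal."""
    config = SimConfig(
        n_patients=160,
        modalities=("C", "P", "M"),
        n_features={"C": 10, "P": 12, "M": 8},
        informative={"C": 3, "P": 3, "M": 0},
        effect_size=1.0,
        seed=7,
    )
    cohort, truth = generate_cohort(config)
    return cohort, truth


@pytest.fixture(scope="session")
def image_cohort():
    """Cohort with 32-px tiles and strongly label-linked lesions."""
    config = SimConfig(
        n_patients=80,
        modalities=("C", "I"),
        n_features={"C": 6, "P": 1, "M": 1},
        informative={"C": 2, "P": 0, "M": 0},
        effect_size=1.0,
        tile_size=32,
        tiles_per_patient=2,
        lesion_signal=1.0,
        seed=11,
    )
    cohort, truth = generate_cohort(config)
    return cohort, truth


@pytest.fixture(scope="session")
def fitted_tabular(tabular_cohort):
    """A trained tabular-only model shared by interpretability tests."""
    cohort, truth = tabular_cohort
    config = TrainConfig(
        modalities=("C", "P", "M"),
        epochs=25,
        seed=5,
        early_stopping=False,
        use_meta=False,
    )
    return train(cohort, config), cohort, truth
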
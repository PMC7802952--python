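import logging

import numpy as np
import pytest

from immunosig.datagen import SyntheticConfig, generate_dataset
from immunosig.io import PipelineConfig

logging.getLogger("immunosig").setLevel(logging.ERROR)


def planted_config(seed: int) -> PipelineConfig:
    """Scaled-down planted-signal study: 200 genes (20 informative, effect
    1.5), 8 cohorts x 100 samples — 6 training (400 fit / 200 validation)
    and 2 test; elimination thresholds scaled to the 200-gene pool."""
    return PipelineConfig(
        synthetic=SyntheticConfig(
            n_cohorts=8,
            samples_per_cohort=100,
            n_genes=200,
            n_informative=20,
            effect_size=1.5,
            seed=seed,
        ),
        test_cohorts=["cohort_07", "cohort_08"],
        validation_fraction=1 / 3,
        phase1_threshold=100,
        phase2_floor=10,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared by read-only tests."""
    return generate_dataset(
        SyntheticConfig(
            n_cohorts=3,
            samples_per_cohort=80,
            n_genes=60,
            n_informative=8,
            effect_size=1.5,
            seed=11,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
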
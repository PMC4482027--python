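import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from somscreen import (
    ExpressionDataset,
    MouseClass,
    SyntheticConfig,
    TrainingParams,
    generate,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Small planted effects for fast synthetic fixtures.
SMALL_EFFECTS = {
    "learning": {j: 3.0 for j in range(4)},
    "drug": {j: 3.0 for j in range(4, 6)},
    "genotype": {j: 3.0 for j in range(6, 8)},
}


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_proteins=12, mice_per_class=3, replicates=6,
        effect_map=SMALL_EFFECTS, missing_rate=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def fast_params() -> TrainingParams:
    return TrainingParams(epochs=60)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """Two mice, three proteins, two replicates each, one missing cell."""
    values = np.array([
        [1.0, 0.0, 5.0],
        [3.0, 1.5, 5.0],
        [2.0, 3.0, np.nan],
        [4.0, 1.0, 7.0],
    ])
    classes = [MouseClass.from_code("c-CS-s")] * 2 + \
              [MouseClass.from_code("t-SC-m")] * 2
    return ExpressionDataset(values, ["P1", "P2", "P3"],
                             np.array(["m1", "m1", "m2", "m2"], dtype=object),
                             classes)
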
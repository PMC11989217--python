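import numpy as np
import pytest

from teawither import SyntheticConfig, generate_dataset

# Printed confidence columns of the three external withering time points
# (categories 1, 5, 9) over the ten trained classes, as reported to eight
# decimal places; used as fixed inputs to the confidence-weighted moisture
# computation.
EXTERNAL_CONFIDENCES = {
    1: (0.91888142, 0.08109235, 0.00002619, 0.00000001, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    5: (0.0, 0.00000007, 0.00961427, 0.41952419, 0.57085168, 0.00000980, 0.0, 0.0, 0.0, 0.0),
    9: (0.0, 0.0, 0.0, 0.0, 0.00000004, 0.00098720, 0.53591472, 0.45765832, 0.00543968, 0.00000003),
}

EXTERNAL_TRUE_MOISTURE = {1: 0.7799, 5: 0.7231, 9: 0.597}


@pytest.fixture(scope="session")
def small_dataset():
    """Ten classes x six 32-px images; shared read-only across tests."""
    cfg = SyntheticConfig(n_classes=10, images_per_class=6, image_size=32, seed=7)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
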
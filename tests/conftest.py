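import numpy as np
import pytest

from tempsel.core import (DemographicHistory, SelectionSchedule,
                          bottleneck_demography)
from tempsel.emission import GLDataset, GLRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture
def bottleneck():
    return bottleneck_demography()


@pytest.fixture
def constant_demography():
    return DemographicHistory.constant(16000)


@pytest.fixture
def neutral_schedule():
    return SelectionSchedule((0.0,), (), 0.5)


@pytest.fixture
def two_epoch_schedule():
    return SelectionSchedule((0.02, -0.01), (350,), 0.5)


def make_flat_dataset(sample_gens=(0, 20, 40), per_time=4):
    return GLDataset(GLRecord(f"t{g}_n{j}", g, (1, 1, 1))
                     for g in sample_gens for j in range(per_time))


@pytest.fixture
def flat_ds():
    return make_flat_dataset()


@pytest.fixture
def toy_ds():
    """Small informative dataset: two records at each of two time points."""
    return GLDataset([
        GLRecord("a", 0, (1.0, 0.0, 0.0)),
        GLRecord("b", 0, (0.2, 0.5, 0.3)),
        GLRecord("c", 10, (0.0, 0.3, 0.7)),
        GLRecord("d", 10, (1 / 3, 1 / 3, 1 / 3)),
    ])
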
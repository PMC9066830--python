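import numpy as np
import pytest

from adaptrial import (ScenarioConfig, SurvivalDataset, generate_anz_like,
                       simulate_dataset)


@pytest.fixture(scope="session")
def null_scenario():
    return ScenarioConfig(median_C=10.0, median_E=10.0, name="null")


@pytest.fixture(scope="session")
def target_scenario():
    return ScenarioConfig(median_C=10.0, median_E=15.0, name="target")


@pytest.fixture(scope="session")
def anz_fixture():
    """Synthetic case-study-like dataset (235 subjects, fixed seed)."""
    return generate_anz_like(np.random.default_rng(20240))


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-subject hand-checkable dataset with known entries."""
    return SurvivalDataset(
        recruit=np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5]),
        is_exp=np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=bool),
        time=np.array([5.0, 7.0, 2.0, 9.0, 4.0, 1.5, 6.0, 3.0, 8.0, 2.5]),
        event=np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 1], dtype=bool),
    )


@pytest.fixture(scope="session")
def seeded_target_dataset(target_scenario):
    return simulate_dataset(target_scenario, 274, np.random.default_rng(7))
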
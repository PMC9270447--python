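import numpy as np
import pytest

from agebench import ScenarioConfig, TimestampedDataset, generate_scenario


def make_dataset(timestamps, target=None, n_features=2, seed=0, name="toy"):
    """Small dataset builder for unit tests."""
    timestamps = np.asarray(timestamps, dtype=float)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((len(timestamps), n_features))
    if target is None:
        target = X[:, 0] + rng.standard_normal(len(timestamps))
    return TimestampedDataset(
        name=name,
        timestamps=timestamps,
        features=X,
        feature_names=[f"x{i+1}" for i in range(n_features)],
        target=np.asarray(target, dtype=float),
    )


@pytest.fixture(scope="session")
def stationary_ds():
    return generate_scenario(ScenarioConfig(kind="stationary", seed=7))


@pytest.fixture(scope="session")
def regime_switch_ds():
    return generate_scenario(ScenarioConfig(kind="regime_switch", seed=7))
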
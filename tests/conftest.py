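import numpy as np
import pytest

import larvaclock.synthetic_data as sd
import larvaclock.trajectory as tj


@pytest.fixture(scope="session")
def default_dataset() -> sd.SyntheticDataset:
    """One full synthetic experiment under the default design (seed fixed)."""
    return sd.simulate_experiment(seed=20100710)


@pytest.fixture(scope="session")
def default_rates(default_dataset):
    """Growth-rate table derived from the session dataset."""
    hatch = (
        default_dataset.hatchlings.groupby("family")["head_width_mm"].mean().to_dict()
    )
    rates, excluded = tj.rates_table(default_dataset.larvae, hatch_sizes=hatch)
    assert not excluded
    return rates


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
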
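import numpy as np
import pytest

from bergfert.fe_samples import FeSample, FeSampleSet
from bergfert.synthetic_data import FeGeneratorParams, generate_fe_samples


def make_set(values, catchment="Sermilik", region="Greenland", label="test"):
    """FeSampleSet from raw concentrations (mol/L), single catchment."""
    samples = [
        FeSample(f"s{i}", catchment, region, float(v)) for i, v in enumerate(values)
    ]
    return FeSampleSet(samples, label=label)


@pytest.fixture(scope="session")
def calibrated_set() -> FeSampleSet:
    """One calibrated synthetic realization of the 206-sample global dataset."""
    return generate_fe_samples(FeGeneratorParams(seed=1), 206)


@pytest.fixture(scope="session")
def calibrated_sets() -> list[FeSampleSet]:
    """Ten fixed-seed realizations for seed-averaged statistics."""
    return [generate_fe_samples(FeGeneratorParams(seed=s), 206) for s in range(1, 11)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
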
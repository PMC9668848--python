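import pytest

from pulsetrace.pipeline import RunConfig, compute_full_budget, load_dataset
from pulsetrace.simulate import NoiseModel, StudyDesign, generate_dataset


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_dataset(StudyDesign(seed=11, noise=NoiseModel.zero()))


@pytest.fixture(scope="session")
def noiseless_budget(noiseless_dataset):
    tables = load_dataset(noiseless_dataset)
    return compute_full_budget(tables, RunConfig())


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_dataset(StudyDesign(seed=5))
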
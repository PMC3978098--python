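import pytest

from nrt_pathways.pipeline import run_pipeline
from nrt_pathways.synth import SynthConfig, generate, generate_toy_fixture

#: Problem size for distribution-recovery checks: large enough that
#: binomial noise sits well inside the stated tolerances.
RECOVERY_N = 20_000
RECOVERY_SEED = 20_080_101


@pytest.fixture(scope="session")
def toy_dataset():
    return generate_toy_fixture()


@pytest.fixture(scope="session")
def toy_result(toy_dataset):
    return run_pipeline(toy_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """Mid-sized default-config dataset shared by invariant tests."""
    return generate(SynthConfig(n_patients=4000), seed=42)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return run_pipeline(default_dataset)


@pytest.fixture(scope="session")
def recovery_result():
    """Large run used for parameter-recovery acceptance checks."""
    dataset = generate(SynthConfig(n_patients=RECOVERY_N), seed=RECOVERY_SEED)
    return run_pipeline(dataset)
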
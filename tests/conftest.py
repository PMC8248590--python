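import pytest

from amiclaims.codes import load_ami_codelist
from amiclaims.simulate import GeneratorConfig, generate, ground_truth, load_profile


@pytest.fixture(scope="session")
def codelist():
    return load_ami_codelist()


@pytest.fixture(scope="session")
def tiny_config():
    return load_profile("tiny_fixture")


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate(tiny_config, 1)


@pytest.fixture(scope="session")
def midi_config():
    # 200-person bundle with a high case rate and enrollment gaps: small
    # enough for brute-force oracles, rich enough to exercise every filter.
    return GeneratorConfig(
        n_persons=200,
        annual_ami_rate_per_1000=80,
        enrollment_gap_prob=0.1,
        background_dx_rate=2.0,
    )


@pytest.fixture(scope="session")
def midi_bundle(midi_config):
    return generate(midi_config, 11)


@pytest.fixture(scope="session")
def midi_truth(midi_config):
    return ground_truth(midi_config, 11)
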
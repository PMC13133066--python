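import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fairseg.data import GenerationSpec, generate_dataset, stratified_split
from fairseg.model import ModelDescriptor, OptimizerConfig


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 samples, 32x32, balanced groups, split 70/10/20."""
    spec = GenerationSpec(n_samples=16, image_size=(32, 32), seed=7)
    samples = generate_dataset(spec)
    stratified_split(samples, seed=7)
    return samples


@pytest.fixture(scope="session")
def tiny_descriptor():
    return ModelDescriptor(depth=2, base_channels=4)


@pytest.fixture()
def tiny_optimizer():
    return OptimizerConfig(lr=1e-3, batch_size=8)
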
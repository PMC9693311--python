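import numpy as np
import pytest

from earmorph import (
    CorrespondedShape,
    PopulationConfig,
    ear_template,
    make_generator_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def template():
    """The procedural ear-like base mesh (217 vertices)."""
    return ear_template()


@pytest.fixture(scope="session")
def generator_model():
    """Ground-truth generative shape model over the base mesh."""
    return make_generator_model(PopulationConfig(seed=3))


@pytest.fixture
def small_shapes(rng):
    """Ten random corresponded shapes over a shared tiny topology."""
    n = 12
    return [
        CorrespondedShape(rng.normal(size=3 * n), topology_id="tiny", label=f"s{i}")
        for i in range(10)
    ]


def random_cloud(rng, n, scale=10.0, offset=(0.0, 0.0, 0.0)):
    return rng.random((n, 3)) * scale + np.asarray(offset)
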
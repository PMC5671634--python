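import numpy as np
import pytest

from gazebmi.synthetic_data import (
    SynthEEGConfig,
    default_scene,
    generate_training_session,
    render_workspace_scene,
)


@pytest.fixture(scope="session")
def default_session():
    """The default cued training session, 20 trials per class, seed 42."""
    return generate_training_session(SynthEEGConfig(seed=42), 20)


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def rendered_scene(scene):
    return render_workspace_scene(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
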
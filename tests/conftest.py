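import numpy as np
import pytest

from pestlite.model import ModelConfig, build_model
from pestlite.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def scene_spec():
    return SceneSpec.benchmark(canvas=96)


@pytest.fixture(scope="session")
def small_dataset(scene_spec):
    """A dozen 96x96 annotated scenes shared across tests."""
    rng = np.random.default_rng(42)
    return [generate_scene(scene_spec, rng) for _ in range(12)]


@pytest.fixture(scope="session")
def tiny_model():
    """Quarter-width detector used by shape/decoding tests (untrained)."""
    return build_model(ModelConfig(width_ratio=0.25, seed=7)).eval()


@pytest.fixture(scope="session")
def trained_tiny_model(scene_spec):
    """A briefly trained quarter-width detector for behavioural tests."""
    from pestlite.train import Trainer, TrainConfig

    rng = np.random.default_rng(11)
    train = [generate_scene(scene_spec, rng) for _ in range(40)]
    model = build_model(ModelConfig(width_ratio=0.25, seed=5))
    cfg = TrainConfig(batch_size=8, lr=2e-3, epochs=14, augment=None, seed=5)
    Trainer(model, cfg).fit(train, None)
    return model.eval()
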
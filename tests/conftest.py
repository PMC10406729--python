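import numpy as np
import pytest

from hsqcnet import (
    HSQCNet,
    SimulatorConfig,
    make_dataset,
    rasterize,
)
from hsqcnet.benchmark import learning_sanity_experiment


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 synthetic molecules with simulated spectra, seeded."""
    cfg = SimulatorConfig(n_molecules=16, seed=7)
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained small network, enough for shape/contract tests."""
    examples, _ = tiny_dataset
    model = HSQCNet(
        channels=1,
        conv_stack=((8, 3, 2), (16, 3, 2)),
        embedding_dim=16,
        n_classes=4,
        learning_rate=1e-3,
        epochs=2,
        batch_size=8,
        seed=0,
    )
    X = np.stack([rasterize(e.peaklist).grid for e in examples])
    model.fit(X, [e.record for e in examples])
    return model


@pytest.fixture(scope="session")
def sanity_results():
    """The full seeded learning-sanity experiment (runs once, ~2 min)."""
    return learning_sanity_experiment(seed=1)
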
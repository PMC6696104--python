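import numpy as np
import pytest

from respiradar import (
    CLASS_ORDER,
    ParamCombo,
    SplitSpec,
    TrainConfig,
    WindowSample,
    generate_dataset,
    split_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 5 patterns x 5 windows = 50 labeled windows."""
    windows, meta = generate_dataset(n_subjects=2, per_pattern=5, seed=7)
    return windows, meta


def _toy_prototypes(n: int = 250) -> list[np.ndarray]:
    """Five well-separated prototype waveforms of length 250."""
    t = np.linspace(0, 1, n)
    return [
        np.sin(2 * np.pi * 3 * t),
        np.sin(2 * np.pi * 8 * t),
        np.sign(np.sin(2 * np.pi * 3 * t)),
        t * 2 - 1,
        np.exp(-((t - 0.5) ** 2) / 0.01),
    ]


@pytest.fixture(scope="session")
def toy_separable():
    """Separable 5-class toy: prototypes + tiny noise; (train, test) lists."""
    rng = np.random.default_rng(42)
    protos = _toy_prototypes()
    train, test = [], []
    for cls, proto in zip(CLASS_ORDER, protos):
        for i in range(24):
            x = proto + rng.normal(0, 0.02, proto.size)
            sample = WindowSample(values=x, label=cls, source_id=f"toy:{cls.value}:{i}")
            (train if i < 16 else test).append(sample)
    return train, test


@pytest.fixture(scope="session")
def tiny_combo():
    return ParamCombo(conv_layers=((9, 4), (5, 8)), dense_neurons=(32, 16))


@pytest.fixture(scope="session")
def tiny_cfg():
    return TrainConfig(epochs=15, batch_size=10, seed=0)
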
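import numpy as np
import pytest

from irkd.synthetic import ClassParams, SyntheticSpec, generate_activity_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Three well-separated classes, 2 channels, short windows: enough
    structure for classifiers to learn, cheap enough for every test."""
    spec = SyntheticSpec(
        class_params=(
            ClassParams(1.0, 1.0, (1.0,), 0.05),
            ClassParams(2.0, 1.0, (1.0,), 0.05),
            ClassParams(4.0, 1.0, (1.0,), 0.05),
        ),
        n_subjects=4,
        windows_per_class=12,
        channels=2,
        window_length=64,
        sample_rate=32.0,
        subject_jitter=0.05,
        seed=7,
    )
    return generate_activity_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
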
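import numpy as np
import pandas as pd
import pytest

from emoselect.containers import EpochSet
from emoselect.synthetic import (
    DatasetProfile,
    SyntheticSpec,
    generate_epoch_set,
)


@pytest.fixture(scope="session")
def tiny_profile():
    """3 subjects x 6 trials x 4 channels, 4-s trials at 128 Hz."""
    return DatasetProfile("tiny", 3, 6, 4, 128.0, 4.0, "valence_arousal_1to9")


@pytest.fixture(scope="session")
def tiny_epochs(tiny_profile):
    """Small epoch set with a planted alpha contrast on channels 0 and 2."""
    spec = SyntheticSpec(
        profile=tiny_profile,
        informative_channels=frozenset({0, 2}),
        informative_window_indices=frozenset({0}),
        class_band_power={"low": {"theta": 2.0},
                          "high": {"alpha": 2.5, "beta": 2.0}},
        seed=7,
    )
    return generate_epoch_set(spec)


@pytest.fixture()
def manual_epochs():
    """Hand-built 4-trial set for I/O and container tests."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((4, 3, 32)) * 20.0
    labels = pd.DataFrame({
        "trial": [0, 1, 0, 1],
        "valence": [2.0, 7.0, 4.0, 9.0],
        "arousal": [3.0, 8.0, 6.0, 1.0],
    })
    return EpochSet(data, ["Fz", "Cz", "Pz"], 128.0,
                    np.array([0, 0, 1, 1]), labels)
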
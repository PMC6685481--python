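import numpy as np
import pandas as pd
import pytest

from nlsound import (
    RatingModel,
    extract_features_from_bank,
    make_ratings,
    make_sound_bank,
)


@pytest.fixture(scope="session")
def bank40():
    """A 40-sound synthetic bank shared across the suite."""
    return make_sound_bank(40, seed=11)


@pytest.fixture(scope="session")
def features40(bank40):
    return extract_features_from_bank(bank40)


@pytest.fixture(scope="session")
def ratings40(features40):
    return make_ratings(features40, RatingModel(seed=11))


@pytest.fixture(scope="session")
def categories40(bank40):
    return pd.Series({w.sound_id: w.category for w in bank40})


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
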
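import warnings

import numpy as np
import pytest

from lexcat import synth_lexicon
from lexcat.pipeline import run_canonical_study


@pytest.fixture(scope="session")
def canonical():
    """The canonical simulation study: 2,000-word synthetic lexicon,
    balanced W/PW/CS stimulus set, exact-bin curve, LCM simulation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_canonical_study(n_words=2000, seed=0)


@pytest.fixture(scope="session")
def small_lexicon():
    return synth_lexicon(300, length=5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
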
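import numpy as np
import pytest

from chtlm.synthetic import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_synth():
    """Fast generator settings for module-level tests."""
    return SynthConfig(seed=11, n_subjects=3, trials_per_class=4, effect_amp=2.0)
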
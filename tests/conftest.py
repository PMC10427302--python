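import numpy as np
import pytest

import harshpref as hp


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete study: 8/7/6 raters, 4 targets."""
    return hp.default_sim_config(seed=42, n_raters_per_condition=(8, 7, 6),
                                 n_targets=4, recognition_rate=0.0)


@pytest.fixture(scope="session")
def tiny_raw(tiny_config):
    return hp.simulate_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_clean(tiny_raw):
    clean, _, _ = hp.preprocess(tiny_raw)
    return clean


@pytest.fixture(scope="session")
def tiny_prepared(tiny_clean):
    return hp.prepare(tiny_clean)
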
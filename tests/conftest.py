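import numpy as np
import pytest

import glytrial as gt


@pytest.fixture(scope="session")
def dynamic_cfg():
    return gt.default_dynamic_config()


@pytest.fixture(scope="session")
def static_cfg():
    return gt.default_static_config()


@pytest.fixture(scope="session")
def small_trial(dynamic_cfg):
    """A small deterministic dynamic-arm dataset for reuse across tests."""
    spec = gt.CohortSpec(n=12, seed=321, duration=96)
    return gt.run_arm(spec, dynamic_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
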
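import numpy as np
import pytest

import edcasim as e
from edcasim.metrics import run_once


@pytest.fixture(scope="session")
def hrtn_config():
    return e.default_hrtn_config()


@pytest.fixture(scope="session")
def small_config():
    from edcasim.fixtures import small_test_config
    return small_test_config()


def rep_seed(root: int, i: int) -> int:
    """Replication seed derivation used throughout the suite."""
    return int(np.random.SeedSequence((root, i)).generate_state(1)[0] % 2**31)


@pytest.fixture(scope="session")
def policy_replications(hrtn_config):
    """30 common-random-number replications of the 3-day protocol for the
    baseline and each of the four policies (shared across the calibration
    and policy-ordering acceptance checks)."""
    out = {}
    for pol in e.POLICIES:
        cfg = e.apply_policy(hrtn_config, pol)
        out[pol] = [run_once(cfg, rep_seed(1, i))[0] for i in range(30)]
    return out
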
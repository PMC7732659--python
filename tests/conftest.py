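import numpy as np
import pytest

from paskit.simulator import GenerativeConfig, recovery_experiment


@pytest.fixture(scope="session")
def ostracism_recovery():
    """100-replicate parameter-recovery run at the ostracism design.

    Shared across the recovery-property and explained-variance tests so the
    (minutes-long) simulate->parse->classify->fit loop happens once.
    """
    cfg = GenerativeConfig()
    return recovery_experiment(cfg, 100, seeds=list(range(1, 101)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20190301)
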
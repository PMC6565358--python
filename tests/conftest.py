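import numpy as np
import pytest

from seqerp.task import TaskConfig, build_session


@pytest.fixture(scope="session")
def default_session():
    """A full default main session (4 low + 4 high blocks, 160 sequences)."""
    return build_session(TaskConfig(), seed=11)


@pytest.fixture(scope="session")
def small_config():
    """Small session config used where a full session would be wasteful."""
    return TaskConfig(n_blocks_low=1, n_blocks_high=1, sequences_per_block=10,
                      composition_low=(0.1, 0.8, 0.1),
                      composition_high=(0.2, 0.6, 0.2))


@pytest.fixture(scope="session")
def small_session(small_config):
    return build_session(small_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
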
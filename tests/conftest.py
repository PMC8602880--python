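import numpy as np
import pytest

from mazetalk import (
    TaskConfig,
    build_environment,
    build_model,
    run_confabulation,
    run_standard,
    sever_link,
)
from mazetalk.hierarchy import run_hierarchy


@pytest.fixture(scope="session")
def task_model():
    return build_model(TaskConfig())


@pytest.fixture(scope="session")
def std_first():
    """Standard session, reward on the right, first move queried."""
    return run_standard("first", "right", seed=0)


@pytest.fixture(scope="session")
def std_second():
    """Standard session, reward on the right, second move queried."""
    return run_standard("second", "right", seed=0)


@pytest.fixture(scope="session")
def confab():
    """Confabulation session: (query, answer, answer), no maze epoch."""
    return run_confabulation(seed=0)


@pytest.fixture(scope="session")
def severed_records():
    """Standard session with the slow-to-policy link severed (uniform bias)."""
    cfg = TaskConfig(context="right", query="first")
    return run_hierarchy(sever_link(build_model(cfg)), build_environment(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
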
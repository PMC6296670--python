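import numpy as np
import pytest

from welchslopes import (
    GroupSample,
    mice_planning_config,
    mice_summaries,
    summarize_group,
)


@pytest.fixture(scope="session")
def mice():
    """Group summaries of the diabetic/normal mice worked example."""
    return mice_summaries()


@pytest.fixture(scope="session")
def mice_config():
    return mice_planning_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_two_groups(rng, n1=12, n2=17, beta1d=1.0, sigma=(1.0, 2.0)):
    """A generic heteroscedastic two-group dataset for invariance checks."""
    x1 = rng.normal(0.0, 1.5, n1)
    y1 = 0.3 + (1.0 + beta1d) * x1 + rng.normal(0, sigma[0], n1)
    x2 = rng.normal(1.0, 1.0, n2)
    y2 = -0.2 + 1.0 * x2 + rng.normal(0, sigma[1], n2)
    return GroupSample(1, x1, y1), GroupSample(2, x2, y2)


@pytest.fixture()
def two_groups(rng):
    g1, g2 = random_two_groups(rng)
    return summarize_group(g1), summarize_group(g2)
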
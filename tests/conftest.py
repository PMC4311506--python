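import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rorqual.synth import random_additive_tree  # noqa: F401  (test helper)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
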
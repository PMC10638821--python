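import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def type1_truth():
    """One full-size Marsh Type 1 specimen (shared; treat as read-only)."""
    from celiaq import default_params_for_marsh, generate_specimen

    return generate_specimen(default_params_for_marsh("1", seed=11))


@pytest.fixture(scope="session")
def type1_render(type1_truth):
    from celiaq import render_ihc

    return render_ihc(type1_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
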
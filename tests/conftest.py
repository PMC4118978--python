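import hypothesis
import pytest

import blinkreflex as br
from blinkreflex.cohort import GeneratorConfig, generate_cohort

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def limits():
    return br.default_limits()


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 12+20 cohort with the study-like scenario mix."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def healthy_subjects(small_cohort):
    return small_cohort.healthy
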
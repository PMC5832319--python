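import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellquant import SceneSpec, cell_count_for_coverage, generate_scene

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def scene_with_coverage(coverage_percent: float, seed: int, **overrides) -> "SyntheticScene":
    """Generate a default-regime scene whose true coverage targets the request."""
    base = SceneSpec(seed=seed, **overrides)
    n = cell_count_for_coverage(base, coverage_percent)
    return generate_scene(dataclasses.replace(base, cell_count=n))


@pytest.fixture
def default_scene():
    """One default-regime scene (~19% coverage, 120 cells, seed fixed)."""
    return generate_scene(SceneSpec(seed=1))
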
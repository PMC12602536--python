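import pytest
from hypothesis import HealthCheck, settings

from obesim import load_base_case

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_config():
    """Packaged Greek-payer base case, fixture-completed."""
    return load_base_case()


@pytest.fixture(scope="session")
def short_config(base_config):
    """Ten-year variant for fast end-to-end structural checks."""
    from obesim import apply_overrides

    return apply_overrides(
        base_config,
        {"horizon_years": 10.0, "cycle_schedule": [0.25] * 4 + [1.0] * 9},
    )
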
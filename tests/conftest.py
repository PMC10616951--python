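import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One 11-donor simulated study shared across tests (read-only)."""
    from mappskit import synthetic

    cfg = synthetic.default_config(1)
    return synthetic.simulate_study(cfg)
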
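import pytest

from perchscale.simulate import SimulationConfig


@pytest.fixture
def clean_config():
    """Factory for artifact-free simulation configs (overridable)."""

    def make(**overrides) -> SimulationConfig:
        defaults = dict(
            days=2,
            roost_prob=1.0,
            day_occupancy=0.5,
            flap_rate_per_h=0.0,
            partial_rate_per_h=0.0,
            impact_rate_per_day=0.0,
            sensor_jitter_sd=0.0,
            day_to_day_sd=0.0,
            seed=123,
        )
        defaults.update(overrides)
        return SimulationConfig(**defaults)

    return make
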
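import pytest
from hypothesis import settings

from cmjagree import SimConfig, process_jump, simulate_trace

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_jump():
    """A clean 15 cm jump: (config, trace, truth, processed result)."""
    cfg = SimConfig(noise_sd=0.0, landing_delay=0.0)
    trace, truth = simulate_trace(cfg)
    result = process_jump(trace)
    return cfg, trace, truth, result
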
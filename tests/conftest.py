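import pytest

from nils_cea import default_parameter_set, run_scenario_suite


@pytest.fixture(scope="session")
def cfg():
    """Default parameter set (printed values plus synthetic stand-ins)."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def suite(cfg):
    """Full deterministic scenario-suite table, computed once per session."""
    return run_scenario_suite(cfg)
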
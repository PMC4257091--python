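import pytest

from pipsim import ClimateTarget, default_config, generate_met, run_simulation


@pytest.fixture(scope="session")
def met_year():
    """One synthetic base year at the default climate targets."""
    return generate_met(ClimateTarget(seed=42), n_years=1)


@pytest.fixture(scope="session")
def control_run(met_year):
    """The undisturbed 4-year control simulation at frozen defaults."""
    return run_simulation(default_config(), met=met_year)


@pytest.fixture(scope="session")
def cfg():
    return default_config()
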
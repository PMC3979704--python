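import pytest

from niptscreen import (
    MaternalAgeDistribution,
    StrategySpec,
    default_parameters,
    default_prevalence_model,
    run_strategy,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def ages():
    return MaternalAgeDistribution.england_default()


@pytest.fixture(scope="session")
def prev(ages, params):
    return default_prevalence_model(ages, params.loss_rates)


@pytest.fixture(scope="session")
def base_runs(params, ages, prev):
    """Events and outcomes for the three strategies under base-case inputs."""
    out = {}
    for strategy in ("current", "contingent_nipt", "firstline_nipt"):
        spec = StrategySpec(strategy=strategy)
        out[strategy] = run_strategy(params, spec, ages=ages, prev=prev)
    return out
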
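from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import symshuffle as ss

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Fixed master seed for the ensemble-level qualitative checks.
MASTER_SEED = 1
N_REPLICATES = 20


@pytest.fixture(scope="session")
def default_params() -> ss.ModelParams:
    return ss.ModelParams()


@pytest.fixture(scope="session")
def lee_stocking_site() -> ss.SiteForcing:
    return ss.site_forcing("lee_stocking")


@pytest.fixture(scope="session")
def baseline_spec() -> ss.ScenarioSpec:
    return ss.ScenarioSpec(
        site="lee_stocking", n_replicates=N_REPLICATES, master_seed=MASTER_SEED
    )


@pytest.fixture(scope="session")
def lee_stocking_baseline(default_params, baseline_spec):
    """20-replicate baseline ensemble at the stable site."""
    return ss.run_scenario(baseline_spec, default_params)


@pytest.fixture(scope="session")
def lee_stocking_warming(default_params, baseline_spec):
    """Same ensemble under the +1/+1.5/+1 degC Jul-Sep overlay."""
    spec = replace(baseline_spec, warming=ss.DEFAULT_WARMING)
    return ss.run_scenario(spec, default_params)


@pytest.fixture(scope="session")
def key_largo_baseline(default_params, baseline_spec):
    """20-replicate baseline ensemble at the seasonally variable site."""
    spec = replace(baseline_spec, site="key_largo")
    return ss.run_scenario(spec, default_params)
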
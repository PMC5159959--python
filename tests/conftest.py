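import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic world (12 countries, 4 risks, 2 periods)."""
    from dietcra.synthetic import WorldSpec, generate_world

    return generate_world(WorldSpec(seed=7))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    from dietcra.pipeline import run_all

    return run_all(default_bundle, n_draws=100, seed=7)


@pytest.fixture()
def tiny_spec():
    """A one-risk, one-outcome, single-period world for fast end-to-end runs."""
    from dietcra.synthetic import SyntheticRisk, WorldSpec

    risk = SyntheticRisk(
        name="fruits",
        direction="harmful_low",
        unit="g/day",
        global_mean=120.0,
        cv=0.30,
        tmrel=300.0,
        coverage=1.0,
        log_rr={"ischemic_heart_disease": (np.log(1.30) / 300.0, 2.0e-4)},
    )
    return WorldSpec(
        n_super_regions=1,
        n_regions_per=1,
        n_countries_per=2,
        age_groups=((35, 55), (55, 75)),
        sexes=("female",),
        years=(2013,),
        risks=(risk,),
        yll_per_death=(30.0, 15.0),
        outcome_baseline_rates=(("ischemic_heart_disease", 50.0),),
        seed=11,
    )
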
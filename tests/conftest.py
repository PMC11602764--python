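import pytest
from hypothesis import HealthCheck, settings

from lqrscreen.cohort import CohortConfig, generate_item_bank, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def item_bank():
    """Six 6-category items with known parameters."""
    return generate_item_bank(6, 6, seed=11)


@pytest.fixture(scope="session")
def clean_cohort(item_bank):
    """Pure-GRM cohort: no careless answers, no skips, no trait shift."""
    cfg = CohortConfig(
        n_respondents=1500,
        scales=(("scale", 6, 6),),
        careless_rate_normal=0.0,
        careless_rate_impaired=0.0,
        skip_rate_normal=0.0,
        skip_rate_impaired=0.0,
        trait_impairment_shift=0.0,
        seed=101,
    )
    responses, cohort = simulate_cohort(cfg, {"scale": item_bank})
    return responses, cohort


@pytest.fixture(scope="session")
def careless_cohort(item_bank):
    """Cohort where impairment manifests only as elevated careless
    responding (no trait shift): the LQR signal in isolation."""
    cfg = CohortConfig(
        n_respondents=1500,
        scales=(("scale", 6, 6),),
        careless_rate_normal=0.05,
        careless_rate_impaired=0.5,
        skip_rate_normal=0.01,
        skip_rate_impaired=0.02,
        trait_impairment_shift=0.0,
        seed=202,
    )
    responses, cohort = simulate_cohort(cfg, {"scale": item_bank})
    return responses, cohort
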
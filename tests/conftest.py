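import pytest
from hypothesis import HealthCheck, settings

from fircompat import synthetic
from fircompat.published import COMPONENTS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Study-proportioned group sizes scaled down to 2,000 trees.
SMALL_N = {1: 718, 2: 441, 3: 346, 4: 314, 5: 181}


@pytest.fixture(scope="session")
def small_stand():
    """One noisy synthetic stand (2,000 trees, default error model)."""
    cfg = synthetic.default_config(n_per_age_group=SMALL_N, seed=101)
    return synthetic.generate_stand(cfg)


@pytest.fixture(scope="session")
def noise_free_stand():
    """Covariates drawn as usual but component biomass exactly on the
    generating allometry (CV = 0)."""
    cfg = synthetic.default_config(
        n_per_age_group={g: 200 for g in range(1, 6)},
        error_cv={c: 0.0 for c in COMPONENTS},
        seed=7,
    )
    return synthetic.generate_stand(cfg)
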
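import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ctpflow import GeneratorConfig, generate, make_worked_toy  # noqa: E402


@pytest.fixture(scope="session")
def toy():
    return make_worked_toy()


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle at seed 42."""
    return generate(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        seed=11, n_herbs=3, compounds_per_herb=10, n_targets=25, n_pathogenic=30,
        ecp_fraction=0.3, n_pathways=8, pathway_size=(3, 8), n_gobp=10,
        gobp_size=(3, 8), n_samples=4,
    )
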
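import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    from gavin.simulate import scenario_presets

    return scenario_presets()


@pytest.fixture()
def small_cohort():
    """Three-gene cohort with distinct planted structure."""
    from dataclasses import replace

    from gavin.simulate import GeneScenario, generate_cohort

    scenarios = [
        GeneScenario(gene="G1", patho_cadd_mean=30.0, benign_cadd_mean=18.0),
        GeneScenario(gene="G2", patho_cadd_mean=20.0, benign_cadd_mean=20.0),
        replace(GeneScenario(gene="G3"), n_patho=3, n_benign=40, n_known_duplicates=2),
    ]
    return generate_cohort(scenarios, seed=11)
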
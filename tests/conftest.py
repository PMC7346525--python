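import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rcseg.pipeline import build_suite_samples
from rcseg.synth import FixtureSpec, generate_pair, generate_scenario_suite

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rosette_pair():
    """One mid-stage rosette fixture with default noise and misalignment."""
    return generate_pair(FixtureSpec(seed=5, archetype="rosette-top", stage="II"))


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, clutter-free fixture with an identity misalignment."""
    spec = FixtureSpec(
        seed=9,
        archetype="rosette-top",
        stage="II",
        noise_sd=0.0,
        illumination_amplitude=0.0,
        shadow_opacity=0.0,
        n_moss=0,
        n_leaftips=0,
        n_soil=0,
        misalignment={"scale": 1.0, "rotation_deg": 0.0, "dx": 0.0, "dy": 0.0},
    )
    return generate_pair(spec)


@pytest.fixture(scope="session")
def mini_suite():
    """A small labeled suite (one archetype, all stages, 4 pairs each)."""
    return generate_scenario_suite(11, n_pairs=4, archetypes=("rosette-top",))


@pytest.fixture(scope="session")
def mini_samples(mini_suite):
    """Region tables of the mini suite, built through the full pipeline."""
    return build_suite_samples(mini_suite)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
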
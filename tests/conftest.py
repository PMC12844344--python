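import numpy as np
import pytest
from hypothesis import settings

from metabotyper import GeneratorSpec, MetabotypeModel, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated():
    """Default calibrated cohort (n=658, three latent metabotypes) + labels."""
    return generate_cohort(GeneratorSpec(seed=42))


@pytest.fixture(scope="session")
def full_fit(calibrated):
    """Full pipeline fit with silhouette grid selection over 3..6."""
    cohort, _ = calibrated
    return MetabotypeModel(cohort, seed=42).fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
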
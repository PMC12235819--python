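import numpy as np
import pandas as pd
import pytest

from ersmix.expansion import expand, standardize
from ersmix.preprocess import log10_metals
from ersmix.simulate import METAL_PANEL, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    """A mid-sized synthetic cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(n_subjects=2027, seed=11))


@pytest.fixture(scope="session")
def termset(cohort):
    Z, _ = standardize(log10_metals(cohort, METAL_PANEL))
    return expand(Z, METAL_PANEL)


@pytest.fixture(scope="session")
def small_panel_cohort() -> pd.DataFrame:
    """A 5-metal cohort for fast selection tests (20 candidate terms)."""
    metals = ["Ag", "Sb", "Sn", "La", "Ce"]
    R = np.full((5, 5), 0.3)
    np.fill_diagonal(R, 1.0)
    cfg = GeneratorConfig(
        n_subjects=4000, seed=23, metal_names=metals,
        latent_correlation=R,
        true_terms=[("Ag", 0.9), ("Sn^2", -0.6)],
        covariate_effects={}, target_prevalence=0.15,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
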
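import numpy as np
import pytest

from prefnr import synthetic_cohort as sc
from prefnr import trial_design as td


@pytest.fixture(scope="session")
def study_design() -> td.Design:
    return td.STUDY_DESIGN


@pytest.fixture(scope="session")
def noise_free_archetypes() -> sc.ArchetypeCohort:
    """The deterministic 6/9/15 three-cluster cohort (shared: it is pure)."""
    return sc.archetypes(noise_sd=0.0, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230921)
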
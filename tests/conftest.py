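import warnings

import numpy as np
import pytest

from spinemorph import census
from spinemorph.cohort import CohortConfig, generate_cohort

# boundary-variance LME fits emit convergence chatter that is expected in the
# simulations; keep genuine failures visible in assertions instead
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort (4/4/6 mice, ~7 dendrites each)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def dendrite_table(default_cohort):
    mice, dendrites, spines = default_cohort
    return census.dendrite_level_table(dendrites, spines, mice)


@pytest.fixture(scope="session")
def spine_table(default_cohort):
    mice, dendrites, spines = default_cohort
    return census.spine_level_table(dendrites, spines, mice)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
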
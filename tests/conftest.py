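import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from dcewash.synthetic_data import (
    CohortSpec,
    Ellipsoid,
    KineticTemplate,
    PhantomSpec,
    PhantomSubregion,
    simulate_cohort,
    simulate_phantom,
)


@pytest.fixture(scope="session")
def washout_phantom():
    """Noise-free phantom: one fast-washout nodule in a plateau lesion."""
    spec = PhantomSpec(
        shape=(28, 28, 28),
        lesion_regions=(Ellipsoid((14.0, 14.0, 14.0), (9.0, 9.0, 9.0)),),
        lesion_template=KineticTemplate(100.0, 220.0, 0.0),
        subregions=(
            PhantomSubregion(
                Ellipsoid((14.0, 14.0, 14.0), (4.0, 4.0, 4.0)),
                KineticTemplate(100.0, 260.0, 25.0),
            ),
        ),
        noise_sd=0.0,
        seed=0,
    )
    return simulate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortSpec(n=400, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
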
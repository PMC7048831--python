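import numpy as np
import pytest

from gliomics.io import derive_region_masks
from gliomics.phantoms import PhantomSpec, generate_phantom_case


def small_phantom_spec(**kw) -> PhantomSpec:
    """A fast 36³ phantom used where geometry, not texture scale, matters."""
    defaults = dict(
        grid_size=36,
        brain_semi_axes=(16.0, 15.0, 14.0),
        region_radii=(3.0, 5.0, 8.0),
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom_case(small_phantom_spec(), {"IDH": "positive"}, seed=7)


@pytest.fixture(scope="session")
def default_case():
    """One full-size phantom case (72³) shared across feature tests."""
    return generate_phantom_case(PhantomSpec(), {"IDH": "positive"}, seed=3)


@pytest.fixture(scope="session")
def default_case_regions(default_case):
    return derive_region_masks(default_case.mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
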
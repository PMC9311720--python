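import numpy as np
import pytest

from spacerstrat.grids import DoseGrid
from spacerstrat.phantom import FalloffConfig, PhantomSpec, generate_phantom, simulate_plan_dose


@pytest.fixture(scope="session")
def ensemble30():
    """30 sampled phantoms, one labelled plan each, at the default grid.

    Shared by the simulator-contract, volume-statistics and risk-band tests.
    """
    plans = []
    for seed in range(30):
        spec = PhantomSpec.sample(seed)
        anatomy = generate_phantom(spec)
        boost = seed % 6
        falloff = FalloffConfig.sample(1000 + seed)
        dose = simulate_plan_dose(anatomy, boost, falloff)
        plans.append((spec, anatomy, boost, falloff, dose))
    return plans


@pytest.fixture(scope="session")
def desk_phantom():
    spec = PhantomSpec.desk(7)
    anatomy = generate_phantom(spec)
    dose = simulate_plan_dose(anatomy, 2, FalloffConfig.sample(77))
    return spec, anatomy, 2, dose


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_dose(values, spacing=(1.0, 1.0, 1.0)):
    return DoseGrid(np.asarray(values, dtype=float), spacing)


@pytest.fixture()
def random_dose_and_mask(rng):
    dose = DoseGrid(rng.uniform(0, 70, size=(12, 14, 10)), (2.0, 1.5, 1.5))
    mask = rng.random((12, 14, 10)) > 0.5
    return dose, mask
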
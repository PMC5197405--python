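import numpy as np
import pytest

from borderown import effects as eff
from borderown import simulate as sim


@pytest.fixture(scope="session")
def scene_fixture():
    return sim.generate_scene_fixture(seed=7, size=65, object_shape="disc")


@pytest.fixture(scope="session")
def straight_scene_fixture():
    return sim.generate_scene_fixture(
        seed=3, size=65, object_shape="half", orientation_deg=30.0
    )


@pytest.fixture(scope="session")
def small_params():
    """A fast cell: few scenes, calibrated timings."""
    return sim.preset_paper_calibrated(n_scenes=6, n_reps=4)


@pytest.fixture(scope="session")
def small_cell(small_params):
    rng = np.random.default_rng(42)
    return sim.simulate_cell(small_params, rng, cell_id="cellA")


@pytest.fixture(scope="session")
def small_cell_fits(small_cell):
    return eff.fit_cell(small_cell)
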
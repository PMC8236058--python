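import numpy as np
import pytest

from xenoclass.delineate import DelineationParams, delineate_cells, summarize_cells
from xenoclass.synth import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A modest mixed scene used by several suites (seeded, ~120 cells)."""
    return generate_scene(
        SceneSpec(size_px=512, n_human=60, n_mouse=60, n_curves=1, seed=7)
    )


@pytest.fixture(scope="session")
def small_scene_cells(small_scene):
    params = DelineationParams(delta_um=2.0, calibration=small_scene.spec.calibration)
    cells = delineate_cells(small_scene.nuclei, params)
    records = summarize_cells(
        small_scene.nuclei, cells, small_scene.spec.calibration
    )
    return cells, records


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
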
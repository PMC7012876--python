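import numpy as np
import pytest

from hemosys import SceneSpec, generate_scene
from hemosys.preprocess import GridSeries


@pytest.fixture(scope="session")
def wavefront_scene():
    return generate_scene(SceneSpec(kind="WAVEFRONT", seed=11))


@pytest.fixture(scope="session")
def short_wavefront_scene():
    """30-min front: leaves whole sub-regions outside the final contour."""
    return generate_scene(SceneSpec(kind="WAVEFRONT", duration_min=30.0, seed=11))


@pytest.fixture(scope="session")
def niches_scene():
    return generate_scene(SceneSpec(kind="NICHES", seed=11))


@pytest.fixture(scope="session")
def coupling_scene():
    return generate_scene(SceneSpec(kind="COUPLING", seed=11))


@pytest.fixture(scope="session")
def perturbation_scene():
    return generate_scene(SceneSpec(kind="PERTURBATION", duration_min=30.0, seed=11))


@pytest.fixture(scope="session")
def spectral_scene():
    return generate_scene(SceneSpec(kind="SPECTRAL", seed=11))


def make_grid(values: np.ndarray, times=None, variable: str = "BV") -> GridSeries:
    """Wrap a (R, C, N) array as a GridSeries with nothing missing."""
    values = np.asarray(values, dtype=float)
    R, C, N = values.shape
    return GridSeries(
        variable=variable,
        values=values,
        block_px=50,
        times=np.arange(N, dtype=float) if times is None else np.asarray(times, float),
        missing_mask=np.zeros((R, C), dtype=bool),
    )
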
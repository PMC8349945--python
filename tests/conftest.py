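import numpy as np
import pytest

from simivim import (
    LesionSpec,
    NoiseSpec,
    SceneConfig,
    build_scene,
    compute_all,
    simulate_dwi,
)
from simivim.ivim_maps import DWIStack


def make_stack(signals: dict[float, float | np.ndarray], shape=(1, 1, 1)) -> DWIStack:
    """A tiny stack from scalar (or array) signals per b value."""
    volumes = {b: np.full(shape, s, dtype=np.float64) if np.isscalar(s) else np.asarray(s)
               for b, s in signals.items()}
    return DWIStack(tuple(sorted(volumes)), volumes)


@pytest.fixture(scope="session")
def mixed_scene():
    """Small scene with one lesion of each class plus a cored metastasis."""
    lesions = (
        LesionSpec("HCC", radius=4),
        LesionSpec("haemangioma", radius=4),
        LesionSpec("FNH", radius=4),
        LesionSpec("metastasis_CRC", radius=5, core_radius_frac=0.5),
    )
    return build_scene(SceneConfig(shape=(48, 48, 16), lesions=lesions, seed=11))


@pytest.fixture(scope="session")
def noiseless_stack(mixed_scene):
    return simulate_dwi(mixed_scene, (0, 50, 800), NoiseSpec("none", 0.0, 0))


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_stack):
    return compute_all(noiseless_stack)


@pytest.fixture(scope="session")
def fd_scene():
    lesions = tuple(LesionSpec(lbl, radius=4) for lbl in
                    ("HCC", "haemangioma", "FNH"))
    return build_scene(SceneConfig(shape=(48, 48, 12), lesions=lesions, seed=3))


@pytest.fixture(scope="session")
def fd_stack(fd_scene):
    """Fully dephased, noiseless: the regime where D'/f' recover D/f exactly."""
    return simulate_dwi(fd_scene, (0, 50, 800), NoiseSpec("none", 0.0, 0),
                        perfusion_mode="fully_dephased")
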
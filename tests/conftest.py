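import numpy as np
import pytest

from petrad import (
    LesionMask,
    PETVolume,
    PhantomSpec,
    make_phantom,
    sphere_lesion,
)
from petrad.features.discretize import DiscretizedVOI


@pytest.fixture
def sphere_phantom():
    """Noise-free uniform sphere: radius 20 mm, peak SUV 10, background 1,
    centred on a voxel centre of the 4 mm grid."""
    spec = PhantomSpec(
        shape=(40, 40, 40),
        lesions=[sphere_lesion((82.0, 82.0, 82.0), 20.0, peak_suv=10.0)],
    )
    return make_phantom(spec)


@pytest.fixture
def textured_phantom():
    """Checkerboard-textured sphere for texture-feature smoke tests."""
    spec = PhantomSpec(
        shape=(40, 40, 40),
        lesions=[
            sphere_lesion(
                (82.0, 82.0, 82.0), 20.0, peak_suv=10.0,
                texture="checker", texture_params={"period": 2, "low_fraction": 0.6},
            )
        ],
    )
    return make_phantom(spec)


def make_voi(levels: np.ndarray, n_bins: int | None = None, spacing=(1.0, 1.0, 1.0)):
    """Build a DiscretizedVOI directly from an integer level array
    (0 = outside the mask)."""
    levels = np.asarray(levels, dtype=np.int32)
    mask = levels > 0
    ng = n_bins if n_bins is not None else int(levels.max())
    return DiscretizedVOI(
        levels=levels, mask=mask, n_bins=ng,
        bin_edges=np.arange(ng + 1, dtype=float), spacing=spacing,
    )


def random_voi(rng: np.random.Generator, shape=(5, 5, 5), ng=4, mask_prob=1.0):
    """Random small VOI over levels 1..ng, optionally with holes."""
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    if mask_prob < 1.0:
        levels[rng.random(shape) > mask_prob] = 0
        if not (levels > 0).any():
            levels[tuple(s // 2 for s in shape)] = 1
    return make_voi(levels, n_bins=ng)


@pytest.fixture
def uniform_cube_volume():
    """10x10x10 voxel cube of SUV 5 inside a 16^3 grid at 2 mm spacing."""
    data = np.ones((16, 16, 16))
    data[3:13, 3:13, 3:13] = 5.0
    vol = PETVolume(data=data, spacing=(2.0, 2.0, 2.0))
    mask = np.zeros((16, 16, 16), dtype=bool)
    mask[3:13, 3:13, 3:13] = True
    return vol, LesionMask(data=mask, spacing=(2.0, 2.0, 2.0))
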
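import numpy as np
import pytest

from poroct.phantom import CorticalPhantomSpec, make_cortical_phantom


@pytest.fixture(scope="session")
def small_cortical():
    """A small 1 μm cortical phantom (3 canals, 12 lacunae) plus its truth."""
    spec = CorticalPhantomSpec(
        outer_diameter_um=120, wall_thickness_um=35, length_um=60,
        canal_count=3, canal_diameter_um=(10, 1),
        lacuna_count=12, lacuna_volume_um3=(600, 100),
        render_voxel_um=1.0, rng_seed=1)
    vol, truth = make_cortical_phantom(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
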
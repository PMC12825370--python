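import numpy as np
import pytest

from xrrfilm import InterfaceModel, Slab

# fitted two-slab oleic-acid monolayer stacks (tail slab first), one shared
# roughness per sample
OA_454 = dict(d1=10.63, rho1=0.312, d2=5.025, rho2=0.350, sigma=3.594)
OA_349 = dict(d1=11.64, rho1=0.303, d2=6.0, rho2=0.357, sigma=3.758)


def two_slab_model(p: dict) -> InterfaceModel:
    return InterfaceModel(
        slabs=(Slab(p["d1"], p["rho1"]), Slab(p["d2"], p["rho2"])),
        shared_sigma=p["sigma"],
    )


@pytest.fixture
def oa_model() -> InterfaceModel:
    """Two-slab oleic-acid monolayer at 45.4 Å²/molecule deposition."""
    return two_slab_model(OA_454)


@pytest.fixture
def oa_model_compressed() -> InterfaceModel:
    return two_slab_model(OA_349)


@pytest.fixture
def qz_grid() -> np.ndarray:
    return np.geomspace(0.016, 0.6, 200)


@pytest.fixture
def fine_z(oa_model) -> np.ndarray:
    return np.linspace(-40.0, 60.0, 8001)
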
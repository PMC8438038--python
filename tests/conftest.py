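import matplotlib
import pytest

matplotlib.use("Agg")

from paquant.spectra import default_library
from paquant.unmixing import build_design


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def phantom_design(library):
    from paquant.simulate import PHANTOM_WAVELENGTHS_NM

    return build_design(library, PHANTOM_WAVELENGTHS_NM, ["hbo2", "hhb", "patrace"])


@pytest.fixture(scope="session")
def small_phantom():
    """One-slice noiseless phantom at default in-plane geometry: 70% SO2
    blood at 10% v/v with 0.9 OD J-aggregate probe."""
    from paquant.simulate import NOISELESS, PHANTOM_WAVELENGTHS_NM, make_phantom_scene, render_stack

    scene = make_phantom_scene(0.7, 0.9, shape=(1, 200, 200))
    stack = render_stack(scene, PHANTOM_WAVELENGTHS_NM, noise=NOISELESS)
    return scene, stack
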
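import numpy as np
import pytest

from frugicue import colour_space as cs


@pytest.fixture(scope="session")
def receptors():
    """Default blue-tit-like receptor set."""
    return cs.make_receptors()


@pytest.fixture()
def flat_spectrum():
    return cs.ReflectanceSpectrum.flat(0.5)


def step_spectrum(lo, hi, level=0.8, base=0.05):
    """Reflectance step: ``level`` inside [lo, hi] nm, ``base`` elsewhere."""
    wl = cs.WAVELENGTH_GRID
    refl = np.where((wl >= lo) & (wl <= hi), level, base)
    return cs.ReflectanceSpectrum(wl, refl)
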
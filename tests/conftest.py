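import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from ctiq import (
    BlurModel,
    NoiseModel,
    PhantomGeometry,
    RadialSpectrum,
    TtfCurve,
    generate_phantom_stack,
)


@pytest.fixture(scope="session")
def default_geometry() -> PhantomGeometry:
    """Full-size scene: 512 px, 200 mm FOV, 25 mm insert, 450 HU contrast."""
    return PhantomGeometry(n_slices=8)


@pytest.fixture(scope="session")
def noiseless_stack(default_geometry):
    """Eight identical noiseless slices, Gaussian blur sigma = 0.4 mm."""
    return generate_phantom_stack(
        default_geometry, BlurModel(sigma=0.4), NoiseModel(variance=0.0)
    )


@pytest.fixture(scope="session")
def flat_ttf() -> TtfCurve:
    return TtfCurve(frequencies=np.array([0.0, 100.0]), values=np.array([1.0, 1.0]))


@pytest.fixture(scope="session")
def white_nps() -> RadialSpectrum:
    """Flat NPS at 100 HU^2 mm^2."""
    return RadialSpectrum(frequencies=np.array([0.0, 100.0]), values=np.array([100.0, 100.0]))
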
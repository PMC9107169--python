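import numpy as np
import pytest

from ctqc.ensemble import ClassProbabilities
from ctqc.phantom import PhantomSpec, generate_phantom
from ctqc.preprocess import ConversionMethod, Plane


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def chest_volume():
    """Noise-free chest phantom: lungs + rib shell, fully deterministic."""
    return generate_phantom(PhantomSpec("chest", False, (32, 64, 64), 0.0, seed=3))


class MockPlaneModel:
    """A PlaneModel stand-in returning a fixed probability vector."""

    def __init__(self, probs, classes, method=ConversionMethod.MIP, plane=Plane.AXIAL):
        self._probs = np.asarray(probs, dtype=float)
        self.classes = tuple(classes)
        self.method = ConversionMethod(method)
        self.plane = Plane(plane)

    def predict_proba(self, model_input):
        return ClassProbabilities(self._probs, self.classes)


@pytest.fixture
def mock_model_factory():
    return MockPlaneModel
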
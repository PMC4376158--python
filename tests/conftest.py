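import numpy as np
import pytest

from ukaspect.config import BoxConfig
from ukaspect.phantom import default_truth, generate_landmark_case, template_landmarks
from ukaspect.uptake import build_region_boxes


@pytest.fixture(scope="session")
def template():
    return template_landmarks()


@pytest.fixture(scope="session")
def template_boxes(template):
    return build_region_boxes(template, BoxConfig())


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=11)


@pytest.fixture(scope="session")
def phantom_case(truth):
    return generate_landmark_case(
        truth.femoral_angles, truth.tibial_angles, truth.tibiofemoral, seed=truth.seed
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (QR sign-fixed); shared oracle helper."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q
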
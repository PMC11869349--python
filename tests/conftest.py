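import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phmorph.synthetic import AnatomyParams, generate_humerus

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_bone():
    """One synthetic humerus at the cohort-mean parameters, noise-free."""
    return generate_humerus(AnatomyParams())


@pytest.fixture(scope="session")
def noisy_bone():
    """Cohort-mean humerus with 0.3 mm isotropic vertex noise."""
    return generate_humerus(AnatomyParams(vertex_noise_sd=0.3, seed=7))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
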
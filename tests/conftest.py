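import numpy as np
import pytest

from cfes import GreyBinning, MixtureParams, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def binning():
    return GreyBinning()


@pytest.fixture(scope="session")
def theta_study():
    """The Monte-Carlo study's reference parameter vector (tight peaks)."""
    return MixtureParams(e_f=-80.0, e_m=50.0, s_f=10.0, s_m=10.0, z=0.3)


@pytest.fixture(scope="session")
def small_phantom(theta_study):
    """A 256x256 phantom at S=10 HU with its ground truth."""
    spec = PhantomSpec(theta_true=theta_study, size=256, seed=42)
    image, truth = generate_phantom(spec)
    return image, truth, spec


def random_theta(rng):
    """A random valid mixture parameter vector inside the binning range."""
    e_f = rng.uniform(-400, 0)
    e_m = e_f + rng.uniform(5, 400)
    return MixtureParams(
        e_f=e_f,
        e_m=e_m,
        s_f=rng.uniform(2, 260),
        s_m=rng.uniform(2, 260),
        z=rng.uniform(0.02, 0.98),
    )
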
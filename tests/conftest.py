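import numpy as np
import pytest

from fmaue.registry import build_registry
from fmaue.synthetic import ImpairmentProfile, gen_recording


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def recording_half():
    """Synthetic recording with a global 0.5 deficit (seed fixed)."""
    profile = ImpairmentProfile(
        rom_scale=0.5, velocity_scale=0.5, force_scale=0.5, seed=11
    )
    return gen_recording(profile)


@pytest.fixture(scope="session")
def recording_equal_sides():
    """Affected side an exact copy of the healthy side (no deficit, no noise)."""
    profile = ImpairmentProfile(noise_sd=0.0, seed=7)
    return gen_recording(profile)


def rigid_transform(rng):
    """A random proper rotation + translation, for invariance tests."""
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=0.5, size=3)
    return q, t
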
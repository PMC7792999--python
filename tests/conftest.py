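import numpy as np
import pytest

from peroxosite.synthetic import (
    EnsembleSpec,
    ToyActiveSiteSpec,
    build_toy_active_site,
    generate_ensemble,
)


@pytest.fixture(scope="session")
def toy_site():
    """Default toy active site with its ground-truth manifest."""
    return build_toy_active_site(ToyActiveSiteSpec())


@pytest.fixture(scope="session")
def medium_ensemble():
    """A 20k-frame coupled ensemble shared across analysis tests."""
    return generate_ensemble(EnsembleSpec(n_frames=20_000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans
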
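import numpy as np
import pytest

from wingmorph import Sex, Species, SyntheticSpec, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced synthetic study: fast but structurally complete."""
    return SyntheticSpec(
        group_sizes={
            (Species.JAPONICUS, Sex.FEMALE): 12,
            (Species.JAPONICUS, Sex.MALE): 11,
            (Species.KOREICUS, Sex.FEMALE): 10,
            (Species.KOREICUS, Sex.MALE): 9,
        },
        n_replicate_specimens=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return generate_study(small_spec)


@pytest.fixture(scope="session")
def default_study():
    """One full study at the default (study-scale) group sizes."""
    return generate_study(SyntheticSpec(seed=11))


def random_preshape(rng, k=18):
    """Centered, unit-centroid-size random configuration."""
    c = rng.standard_normal((k, 2))
    c -= c.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))
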
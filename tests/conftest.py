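import numpy as np
import pytest

from colefuse.fixtures import (
    HNH_SITE,
    ZF_SITE,
    BdnaSpec,
    build_bdna,
    make_toy_complex,
)


@pytest.fixture
def bdna18():
    """Ideal B-DNA duplex over the 18-base straight-construct sequence."""
    return build_bdna(BdnaSpec("GAACTATGAGGCAGAACT"))


@pytest.fixture
def bdna11():
    return build_bdna(BdnaSpec("GAACTATGAGG"))


@pytest.fixture
def hnh_complex():
    """Toy complex with one HNH-like (3xHis) zinc site."""
    return make_toy_complex(BdnaSpec("GAACT"), protein_size=12, zn_sites=(HNH_SITE,), seed=7)


@pytest.fixture
def two_site_complex():
    """Toy complex with one HNH-like and one finger-like (2His+2Cys) site."""
    return make_toy_complex(
        BdnaSpec("GAACT"), protein_size=12, zn_sites=(HNH_SITE, ZF_SITE), seed=7
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
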
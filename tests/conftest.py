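import numpy as np
import pytest

from tempbeta.io_formats import CommunityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20150526)


@pytest.fixture
def small_cm(rng):
    """10 sites x 8 species random community, no empty sites."""
    occ = rng.random((10, 8)) < 0.45
    occ[occ.sum(axis=1) == 0, 0] = True
    return CommunityMatrix(
        site_ids=tuple(f"S{i}" for i in range(10)),
        species_ids=tuple(f"sp{j}" for j in range(8)),
        occ=occ,
        census_label="t1",
    )


@pytest.fixture
def paired_cms(rng, small_cm):
    """Aligned pair: the second census is a perturbed copy of the first."""
    occ2 = small_cm.occ.copy()
    flips = rng.random(occ2.shape) < 0.2
    occ2 ^= flips
    occ2[occ2.sum(axis=1) == 0, 1] = True
    cm2 = CommunityMatrix(small_cm.site_ids, small_cm.species_ids, occ2, "t2")
    return small_cm, cm2
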
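import numpy as np
import pytest

from coreattn import build_atlas, simulate_subject


@pytest.fixture(scope="session")
def atlas():
    """Default analysis grid: 64 x 64 x 32 voxels of 2 x 2 x 4 mm."""
    return build_atlas((64, 64, 32), (2.0, 2.0, 4.0))


@pytest.fixture(scope="session")
def atlas_small():
    """A coarser grid that still satisfies the minimum region size."""
    return build_atlas((48, 48, 24), (2.0, 2.0, 4.0))


@pytest.fixture(scope="session")
def clean_subject(atlas):
    """Noise-free, confounder-free subject with a known 3-region lesion."""
    return simulate_subject(
        atlas, seed=1234, side="left", severity=8.0,
        involvement={"I": 1.0, "M1": 1.0, "M3": 1.0},
        noise_sd=0.0, csf_frac=0.0, calc_frac=0.0,
    )


@pytest.fixture(scope="session")
def symmetric_subject(atlas):
    """Noise-free subject with no lesion: perfectly mirror-symmetric HU."""
    return simulate_subject(
        atlas, seed=99, side="left", severity=0.0,
        noise_sd=0.0, csf_frac=0.0, calc_frac=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20407)
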
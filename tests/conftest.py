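import numpy as np
import pytest

from petfuse.imaging import LesionMask, Volume3D
from petfuse.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def ramp_volume():
    """4x4x4 volume whose value encodes its (x, y, z) index."""
    data = np.arange(64, dtype=float).reshape(4, 4, 4)
    return Volume3D(data, spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def ball_mask():
    """Digital ball of radius 4 voxels inside a 12^3 grid, unit spacing."""
    idx = np.indices((12, 12, 12))
    dist2 = sum((c - 5.5) ** 2 for c in idx)
    return LesionMask(dist2 <= 16.0, "GTVp", (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_cohort():
    """30 phantom patients on small grids with mixed uptake/texture/volume signal."""
    spec = CohortSpec(n_patients=30, seed=11)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def pet_signal_cohort():
    """Cohort where only PET uptake carries hazard signal (CT is pure noise)."""
    spec = CohortSpec(
        n_patients=80,
        seed=7,
        pet_uptake_effect=0.4,
        texture_effect=0.0,
        volume_effect=0.0,
    )
    return spec, generate_cohort(spec)
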
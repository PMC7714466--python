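import numpy as np
import pytest

from nucmorph import (
    Calibration,
    FieldParams,
    make_digitized_sphere,
    make_synthetic_field,
)

#: acquisition calibration used throughout: XY 0.103 µm, Z 0.2 µm
ACQ_CAL = Calibration(0.103, 0.103, 0.2)


def lattice_ball_count(r_eff: float) -> int:
    """Independent oracle: integer lattice points with |p| <= r_eff."""
    n = int(np.floor(r_eff))
    ax = np.arange(-n, n + 1)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    return int(np.count_nonzero(x * x + y * y + z * z <= r_eff * r_eff))


@pytest.fixture(scope="session")
def sphere_r10():
    return make_digitized_sphere(10)


@pytest.fixture(scope="session")
def sphere_r20():
    return make_digitized_sphere(20)


@pytest.fixture(scope="session")
def clean_single_nucleus():
    """One spherical nucleus, no blur, no noise, no domains."""
    params = FieldParams(
        shape=(40, 64, 64),
        calibration=ACQ_CAL,
        n_nuclei=1,
        radius_um=(1.4, 1.4),
        blur_sigma_um=(0.0, 0.0, 0.0),
        noise_sd=0.0,
    )
    return make_synthetic_field(params, seed=7)


@pytest.fixture(scope="session")
def nine_nucleus_field():
    """Noise-free field of nine well-separated spherical nuclei."""
    params = FieldParams(
        shape=(48, 288, 288),
        calibration=ACQ_CAL,
        n_nuclei=9,
        radius_um=(1.2, 1.5),
        min_gap_um=4.8,  # > 2 x 20-voxel padding at 0.103 µm/voxel
        wall_gap_um=0.6,
        blur_sigma_um=(0.0, 0.0, 0.0),
        noise_sd=0.0,
        max_retries=3000,
    )
    return make_synthetic_field(params, seed=11)
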
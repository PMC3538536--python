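import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sinuct.phantom import OpticalConstants, Phantom, make_sinusoid_phantom


@pytest.fixture(scope="session")
def mild_phantom():
    """Small mild-grade phantom shared by read-only tests."""
    return make_sinusoid_phantom((64, 64, 64), 9.0, "mild", 3, (80.0, 150.0), seed=5)


def make_ball_phantom(radius_vox: int, grid: int, voxel_size: float = 9.0) -> Phantom:
    """Phantom with a single spherical lumen centred in a tissue cylinder
    (compact support, as the projector's rotation geometry requires)."""
    from sinuct.phantom import tissue_cylinder_mask

    optics = OpticalConstants()
    c = (grid - 1) / 2
    z, y, x = np.mgrid[0:grid, 0:grid, 0:grid]
    ball = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2
    tissue = tissue_cylinder_mask((grid,) * 3)
    delta = np.where(tissue, optics.parenchyma_delta, 0.0)
    beta = np.where(tissue, optics.parenchyma_beta, 0.0)
    delta[ball] = optics.lumen_delta
    beta[ball] = optics.lumen_beta
    return Phantom(
        delta_volume=delta,
        beta_volume=beta,
        label_volume=ball.astype(np.int32),
        thrombus_mask=np.zeros(ball.shape, dtype=bool),
        voxel_size=voxel_size,
        grade="mild",
        optics=optics,
    )
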
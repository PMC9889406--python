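import numpy as np
import pytest

from needletrack.geometry import ArrayGeometry, ImageGrid, PointSource, Pulse
from needletrack.acoustics import simulate_channel_data
from needletrack.reconstruction import envelope_normalize, reconstruct_fk


@pytest.fixture(scope="session")
def geom() -> ArrayGeometry:
    return ArrayGeometry()


@pytest.fixture(scope="session")
def pulse() -> Pulse:
    return Pulse()


@pytest.fixture(scope="session")
def eval_grid() -> ImageGrid:
    """Coarser localization grid covering depths 12-42 mm."""
    return ImageGrid(x0_mm=-19.05, z0_mm=12.0, dx_mm=0.3, dz_mm=0.15, nx=128, nz=200)


@pytest.fixture(scope="session")
def source() -> PointSource:
    return PointSource(x_mm=3.0, z_mm=30.0)


@pytest.fixture(scope="session")
def channel_data(source, geom, pulse):
    return simulate_channel_data(source, geom, pulse)


@pytest.fixture(scope="session")
def tracking_image(channel_data, eval_grid):
    return envelope_normalize(reconstruct_fk(channel_data, eval_grid))


def gaussian_blob(grid: ImageGrid, x_mm: float, z_mm: float,
                  sigma_z_px: float, sigma_x_px: float) -> np.ndarray:
    """Analytic (not FFT/filter-based) anisotropic Gaussian on a grid."""
    Z, X = np.meshgrid(grid.z_mm, grid.x_mm, indexing="ij")
    sz = sigma_z_px * grid.dz_mm
    sx = sigma_x_px * grid.dx_mm
    return np.exp(-0.5 * (((Z - z_mm) / sz) ** 2 + ((X - x_mm) / sx) ** 2))
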
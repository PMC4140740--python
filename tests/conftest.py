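import numpy as np
import pytest

from earmorph.volume_io import VoxelGrid


def sphere_grid(radius: float, h: float, pad: int = 3) -> VoxelGrid:
    """Voxelized solid sphere, centred mid-array."""
    n = int(2 * radius / h) + 2 * pad
    ax = (np.arange(n) - (n - 1) / 2) * h
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    return VoxelGrid(x**2 + y**2 + z**2 <= radius**2, (h, h, h))


def shell_grid(r_in: float, wall: float, h: float, pad: int = 3) -> VoxelGrid:
    """Voxelized spherical shell, centred mid-array."""
    r_out = r_in + wall
    n = int(2 * r_out / h) + 2 * pad
    ax = (np.arange(n) - (n - 1) / 2) * h
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    rr = np.sqrt(x**2 + y**2 + z**2)
    return VoxelGrid((rr >= r_in) & (rr <= r_out), (h, h, h))


def box_grid(size_xyz, h: float, pad: int = 3) -> VoxelGrid:
    """Voxelized solid box of physical size (lx, ly, lz) mm."""
    lx, ly, lz = size_xyz
    shape = (int(round(lz / h)), int(round(ly / h)), int(round(lx / h)))
    data = np.zeros(tuple(s + 2 * pad for s in shape), dtype=bool)
    data[pad:-pad, pad:-pad, pad:-pad] = True
    return VoxelGrid(data, (h, h, h))


@pytest.fixture(scope="session")
def sphere_r5_h01() -> VoxelGrid:
    return sphere_grid(5.0, 0.1)


@pytest.fixture(scope="session")
def shell_8_1_h01() -> VoxelGrid:
    return shell_grid(8.0, 1.0, 0.1)
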
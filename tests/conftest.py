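import numpy as np
import pytest

from ccparc.parcellation import CortexLookup
from ccparc.section import PlaneSpec, SectionGrid, extract_section
from ccparc.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """The default strip phantom (seed 0)."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_grid(phantom):
    return extract_section(phantom.wm_mask, phantom.plane, oversample=2)


@pytest.fixture(scope="session")
def phantom_cortex(phantom):
    return CortexLookup(phantom.cortex_labels)


def make_strip_grid(n_i=6, n_j=6, voxel=0.5, plane_x=0.0):
    """A small rectangular in-plane grid for kernel/vote unit tests.

    In-plane axes are (y, z); i runs along y (anterior-posterior) and j
    along z.  Centres sit at (0, i*voxel, j*voxel).
    """
    ij = np.array([[i, j] for i in range(n_i) for j in range(n_j)])
    centers = np.column_stack([
        np.zeros(len(ij)), ij[:, 0] * voxel, ij[:, 1] * voxel])
    affine_os = np.diag([voxel, voxel, voxel, 1.0])
    return SectionGrid(
        ij=ij, centers=centers, voxel_area=voxel * voxel,
        plane=PlaneSpec(origin=np.zeros(3), normal=np.array([1.0, 0, 0])),
        affine_os=affine_os, inplane_axes=(1, 2), slab_axis=0,
        slab_half_thickness=voxel / 2,
    )


def make_grid_from_ij(ij, voxel=0.5):
    ij = np.asarray(ij, dtype=int)
    centers = np.column_stack([
        np.zeros(len(ij)), ij[:, 0] * voxel, ij[:, 1] * voxel])
    return SectionGrid(
        ij=ij, centers=centers, voxel_area=voxel * voxel,
        plane=PlaneSpec(origin=np.zeros(3), normal=np.array([1.0, 0, 0])),
        affine_os=np.diag([voxel, voxel, voxel, 1.0]),
        inplane_axes=(1, 2), slab_axis=0, slab_half_thickness=voxel / 2,
    )
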
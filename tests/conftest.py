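"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spinefe import fe
from spinefe.materials import assign_materials
from spinefe.mesh import VoxelMesh, build_mesh
from spinefe.volume import Volume


def make_column_mesh(nx: int, ny: int, nz: int, rho: float = 0.2,
                     voxel: float = 1.0, density_field=None) -> VoxelMesh:
    """Rectangular voxel column: nx x ny x nz elements of edge ``voxel``."""
    dens = np.full((nx, ny, nz), rho, dtype=float)
    if density_field is not None:
        dens[...] = density_field
    mask = np.ones((nx, ny, nz), dtype=np.int32)
    vol = Volume(dens, (voxel,) * 3)
    msk = Volume(mask, (voxel,) * 3)
    return build_mesh(vol, msk)


def roller_column_bc(mesh: VoxelMesh, apparent_strain: float) -> fe.BoundarySpec:
    """Statically determinate uniaxial compression of a column mesh.

    Bottom nodes roll freely in-plane (z fixed via extra constraints), the
    top nodes are driven axially; a 3-2-1 set of lateral constraints removes
    rigid-body modes without restraining Poisson contraction, so the stress
    state is exactly uniform uniaxial.
    """
    coords = mesh.node_coords
    z_lo, z_hi = coords[:, 2].min(), coords[:, 2].max()
    bottom = np.nonzero(np.isclose(coords[:, 2], z_lo))[0]
    top = np.nonzero(np.isclose(coords[:, 2], z_hi))[0]

    # fully fix the bottom node nearest the origin corner
    corner = bottom[np.argmin(coords[bottom, 0] + coords[bottom, 1])]
    others = bottom[bottom != corner]
    extra = [(int(n), 2, 0.0) for n in others]
    # block rotation about z: fix y of a bottom node on the +x edge
    on_x = others[np.isclose(coords[others, 1], coords[corner, 1])]
    pin = on_x[np.argmax(coords[on_x, 0])]
    extra.append((int(pin), 1, 0.0))

    height = z_hi - z_lo
    return fe.BoundarySpec(
        fixed_nodes=np.array([corner]),
        driven_nodes=top,
        applied_displacement=apparent_strain * height,
        loaded_height=height,
        extra=extra,
    )


def column_materials(mesh: VoxelMesh, n_bins: int = 256):
    return assign_materials(mesh.element_density, n_bins=n_bins,
                            pmma_elements=mesh.pmma_elements)


@pytest.fixture
def small_column():
    """4 x 4 x 8 homogeneous column (fast unit-test workhorse)."""
    return make_column_mesh(4, 4, 8, rho=0.2)
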
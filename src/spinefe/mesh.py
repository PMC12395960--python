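"""Voxel-based hexahedral meshing of vertebral bodies.

The calibrated density volume and the vertebral-body mask are resampled to an
isotropic grid (1.0 mm default), each retained mask voxel becomes one HEX8
element, unconnected components are removed, flat endplate surfaces are found
by an anisotropic in-column erosion, and compliant PMMA cap layers are
extruded on the endplates to distribute the applied load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import Volume

__all__ = [
    "VoxelMesh",
    "SurfaceSets",
    "AlignmentTransform",
    "resample_isotropic",
    "align_to_reference",
    "build_mesh",
    "find_endplate_surfaces",
    "add_pmma_caps",
    "segment_cortical",
]

#: default density floor (g/cm³) for in-mask voxels whose calibrated density
#: is non-positive (possible after affine calibration); avoids singular
#: element stiffness.
DENSITY_FLOOR = 0.005

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

# local corner offsets matching hex8.NODE_SIGNS ((s+1)/2)
_CORNER_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)


@dataclass
class VoxelMesh:
    """HEX8 voxel mesh: one cubic element per retained mask voxel."""

    voxels: np.ndarray            # (n_elem, 3) integer grid indices (x, y, z)
    node_coords: np.ndarray       # (n_node, 3) mm
    element_nodes: np.ndarray     # (n_elem, 8) node ids, right-handed HEX8 order
    element_density: np.ndarray   # (n_elem,) g/cm³ (bone; undefined for PMMA)
    voxel_size: float             # mm
    origin: tuple = (0.0, 0.0, 0.0)
    pmma_elements: np.ndarray = field(default=None)  # bool per element

    def __post_init__(self):
        if self.pmma_elements is None:
            self.pmma_elements = np.zeros(len(self.voxels), dtype=bool)

    @property
    def n_elements(self) -> int:
        return len(self.element_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def bone_mask_grid(self) -> np.ndarray:
        """Boolean voxel grid of the bone (non-PMMA) elements."""
        vox = self.voxels[~self.pmma_elements]
        shape = tuple(self.voxels.max(axis=0) + 1)
        grid = np.zeros(shape, dtype=bool)
        grid[tuple(vox.T)] = True
        return grid

    def z_extent_mm(self, include_pmma: bool = True) -> float:
        """Height of the mesh along the loading axis in mm."""
        vox = self.voxels if include_pmma else self.voxels[~self.pmma_elements]
        return float((vox[:, 2].max() - vox[:, 2].min() + 1) * self.voxel_size)


@dataclass
class SurfaceSets:
    """Superior / inferior load-application node sets and their footprints."""

    superior_nodes: np.ndarray    # node ids
    inferior_nodes: np.ndarray
    superior_voxels: np.ndarray   # (k, 3) voxel indices whose top face is loadable
    inferior_voxels: np.ndarray

    def __post_init__(self):
        if len(self.superior_nodes) == 0 or len(self.inferior_nodes) == 0:
            raise ValueError("both surface node sets must be nonempty")
        if np.intersect1d(self.superior_nodes, self.inferior_nodes).size:
            raise ValueError("superior and inferior node sets overlap")


@dataclass
class AlignmentTransform:
    """Rigid rotation + translation with per-axis principal-component scale."""

    rotation: np.ndarray          # 3x3, det = +1
    translation: np.ndarray       # mm
    pc_scale: np.ndarray          # 3 unitless factors (reference / moving)
    residual_mm: float = np.nan

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def resample_isotropic(vol: Volume, target: float = 1.0) -> Volume:
    """Resample to isotropic voxels: nearest-neighbour for label/boolean
    volumes, trilinear for scalar volumes."""
    if target <= 0:
        raise ValueError("target spacing must be positive")
    factors = tuple(s / target for s in vol.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        out = vol.copy_with(vol.data.copy())
        out.spacing = (target,) * 3
        return out
    order = 0 if vol.is_label() else 1
    data = ndimage.zoom(
        vol.data.astype(float) if order else vol.data,
        factors, order=order, grid_mode=True, mode="grid-constant",
    )
    if order == 0:
        data = data.astype(vol.data.dtype)
    return Volume(data, (target,) * 3, vol.origin, dict(vol.meta))


def _principal_axes(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pts = np.argwhere(mask).astype(float) * np.asarray(spacing)
    if len(pts) == 0:
        raise ValueError("mask is empty")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-9 * max(evals[0], 1.0):
        raise ValueError("degenerate (planar) mask: cannot align")
    return centroid, evals, evecs


def _boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    shell = mask & ~ndimage.binary_erosion(mask, structure=_FACE_STRUCT)
    return np.argwhere(shell).astype(float) * np.asarray(spacing)


def align_to_reference(mask: Volume, reference: Volume,
                       icp_iterations: int = 0) -> AlignmentTransform:
    """Centroid + principal-axes rigid alignment of ``mask`` onto
    ``reference``, with per-axis principal-extent scale factors and an
    optional ICP surface refinement.

    The rotation maps the moving mask's principal frame onto the
    reference's; axis signs are chosen to keep the rotation proper and as
    close to identity as possible (vertebrae are pre-oriented head-up).
    """
    c_m, ev_m, ax_m = _principal_axes(mask.data.astype(bool), mask.spacing)
    c_r, ev_r, ax_r = _principal_axes(reference.data.astype(bool), reference.spacing)

    # resolve the sign ambiguity of eigenvectors: flip moving axes toward
    # their reference counterparts
    for i in range(3):
        if np.dot(ax_m[:, i], ax_r[:, i]) < 0:
            ax_m[:, i] = -ax_m[:, i]
    rot = ax_r @ ax_m.T
    if np.linalg.det(rot) < 0:
        ax_m[:, 2] = -ax_m[:, 2]
        rot = ax_r @ ax_m.T
    trans = c_r - rot @ c_m
    scale = np.sqrt(ev_r / ev_m)

    ref_pts = _boundary_points(reference.data.astype(bool), reference.spacing)
    mov_pts = _boundary_points(mask.data.astype(bool), mask.spacing)
    tree = cKDTree(ref_pts)

    for _ in range(icp_iterations):
        moved = mov_pts @ rot.T + trans
        _, idx = tree.query(moved)
        target = ref_pts[idx]
        mu_s, mu_t = moved.mean(axis=0), target.mean(axis=0)
        h = (moved - mu_s).T @ (target - mu_t)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r_step = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        # compose the Kabsch step with the current transform
        rot = r_step @ rot
        trans = r_step @ (trans - mu_s) + mu_t

    moved = mov_pts @ rot.T + trans
    dist, _ = tree.query(moved)
    return AlignmentTransform(rot, trans, scale, residual_mm=float(dist.mean()))


def build_mesh(density: Volume, mask: Volume, floor: float = DENSITY_FLOOR) -> VoxelMesh:
    """Convert a mask + density volume into a HEX8 voxel mesh.

    Only the largest face-connected (6-connected) component of the mask is
    retained; per-element density is ``max(rho, floor)`` in g/cm³.
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    if density.shape != m.shape:
        raise ValueError("density and mask shapes differ")
    labels, n = ndimage.label(m, structure=_FACE_STRUCT)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        m = labels == (np.argmax(counts) + 1)
    voxels = np.argwhere(m).astype(np.int64)
    nodes, elems = _voxel_nodes(voxels)
    h = float(mask.spacing[0])
    dens = np.maximum(density.data[tuple(voxels.T)], floor)
    return VoxelMesh(
        voxels=voxels,
        node_coords=nodes * h,
        element_nodes=elems,
        element_density=np.asarray(dens, dtype=float),
        voxel_size=h,
        origin=mask.origin,
    )


def _voxel_nodes(voxels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shared corner nodes for a set of voxel indices.

    Returns integer node coordinates (n_node, 3) and the (n_elem, 8)
    connectivity in right-handed HEX8 order.
    """
    corners = voxels[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (n, 8, 3)
    dims = corners.reshape(-1, 3).max(axis=0) + 1
    lin = (corners[..., 0] * dims[1] + corners[..., 1]) * dims[2] + corners[..., 2]
    uniq, inv = np.unique(lin, return_inverse=True)
    elems = inv.reshape(-1, 8).astype(np.int64)
    nx = uniq // (dims[1] * dims[2])
    rem = uniq % (dims[1] * dims[2])
    nodes = np.stack([nx, rem // dims[2], rem % dims[2]], axis=1).astype(np.int64)
    return nodes, elems


def find_endplate_surfaces(mesh: VoxelMesh, shell_density: float | None = None,
                           kernel_z: int = 5, flat_tol: int = 0) -> SurfaceSets:
    """Locate flat superior and inferior endplate surfaces.

    A one-voxel cortical shell is isolated (outer boundary layer,
    optionally restricted to voxels denser than ``shell_density``); a
    directional erosion with an anisotropic ``kernel_z`` x 1 x 1 (z-y-x)
    kernel then keeps only shell voxels backed by a full in-column run of
    bone, eliminating thin oblique ledges.  Column tops/bottoms within
    ``flat_tol`` voxels of the extreme plane form the flat surface sets.
    """
    grid = mesh.bone_mask_grid()
    z_span = int(mesh.voxels[:, 2].max() - mesh.voxels[:, 2].min() + 1)
    if z_span < kernel_z:
        raise ValueError(
            f"mesh spans {z_span} voxels in z; need >= {kernel_z} for endplate detection"
        )

    shell = grid & ~ndimage.binary_erosion(grid, structure=_FACE_STRUCT)
    if shell_density is not None:
        dens_grid = np.zeros(grid.shape)
        bone = ~mesh.pmma_elements
        dens_grid[tuple(mesh.voxels[bone].T)] = mesh.element_density[bone]
        shell &= dens_grid >= shell_density

    sup_vox = _flat_surface(grid, shell, top=True, kernel_z=kernel_z, flat_tol=flat_tol)
    inf_vox = _flat_surface(grid, shell, top=False, kernel_z=kernel_z, flat_tol=flat_tol)
    if len(sup_vox) == 0 or len(inf_vox) == 0:
        raise ValueError(
            "no flat endplate surface found; geometry unsuitable for uniform axial loading"
        )
    sup_nodes = _face_nodes(mesh, sup_vox, top=True)
    inf_nodes = _face_nodes(mesh, inf_vox, top=False)
    return SurfaceSets(sup_nodes, inf_nodes, sup_vox, inf_vox)


def _flat_surface(grid, shell, top: bool, kernel_z: int, flat_tol: int) -> np.ndarray:
    nz = grid.shape[2]
    any_col = grid.any(axis=2)
    if top:
        zext = np.where(any_col, np.argmax(grid[:, :, ::-1], axis=2), -1)
        zext = np.where(any_col, nz - 1 - zext, -1)
        extreme = zext[any_col].max()
        keep = any_col & (zext >= extreme - flat_tol)
        direction = -1
    else:
        zext = np.where(any_col, np.argmax(grid, axis=2), -1)
        extreme = zext[any_col].min()
        keep = any_col & (zext <= extreme + flat_tol)
        direction = +1
    out = []
    for x, y in np.argwhere(keep):
        z = zext[x, y]
        if not shell[x, y, z]:
            continue
        run = z + direction * np.arange(kernel_z)
        if run.min() < 0 or run.max() >= nz:
            continue
        if grid[x, y, run].all():
            out.append((x, y, z))
    return np.array(out, dtype=np.int64).reshape(-1, 3)


def _face_nodes(mesh: VoxelMesh, voxels: np.ndarray, top: bool) -> np.ndarray:
    """Node ids of the top (or bottom) faces of the given voxels."""
    base = int(mesh.voxels.max()) + 2
    lin_mesh = _linearize(mesh.voxels, base)
    order = np.argsort(lin_mesh)
    pos = np.searchsorted(lin_mesh, _linearize(voxels, base), sorter=order)
    idx = order[pos]
    if not np.array_equal(mesh.voxels[idx], voxels):
        raise ValueError("surface voxels not present in the mesh")
    locals_ = [4, 5, 6, 7] if top else [0, 1, 2, 3]
    return np.unique(mesh.element_nodes[idx][:, locals_])


def _linearize(voxels: np.ndarray, base: int) -> np.ndarray:
    return (voxels[:, 0] * base + voxels[:, 1]) * base + voxels[:, 2]


def add_pmma_caps(mesh: VoxelMesh, surfaces: SurfaceSets,
                  thickness_voxels: int = 3) -> tuple[VoxelMesh, SurfaceSets]:
    """Extrude PMMA cap layers on the endplate footprints.

    Returns the capped mesh and new surface sets on the outer cap faces
    (these become the fixed and driven boundary-condition sets).
    """
    if thickness_voxels == 0:
        return mesh, surfaces
    if thickness_voxels < 0:
        raise ValueError("cap thickness must be >= 0")

    new_vox = [mesh.voxels]
    pmma = [mesh.pmma_elements]
    dens = [mesh.element_density]
    sup_outer, inf_outer = [], []
    for t in range(1, thickness_voxels + 1):
        up = surfaces.superior_voxels + np.array([0, 0, t])
        dn = surfaces.inferior_voxels - np.array([0, 0, t])
        new_vox += [up, dn]
        pmma += [np.ones(len(up), dtype=bool), np.ones(len(dn), dtype=bool)]
        dens += [np.zeros(len(up)), np.zeros(len(dn))]
        if t == thickness_voxels:
            sup_outer, inf_outer = up, dn

    voxels = np.concatenate(new_vox)
    shift = -voxels.min(axis=0)
    voxels = voxels + shift  # keep indices non-negative after downward extrusion
    nodes, elems = _voxel_nodes(voxels)
    capped = VoxelMesh(
        voxels=voxels,
        node_coords=nodes * mesh.voxel_size,
        element_nodes=elems,
        element_density=np.concatenate(dens),
        voxel_size=mesh.voxel_size,
        origin=mesh.origin,
        pmma_elements=np.concatenate(pmma),
    )
    sup_nodes = _face_nodes(capped, np.asarray(sup_outer) + shift, top=True)
    inf_nodes = _face_nodes(capped, np.asarray(inf_outer) + shift, top=False)
    new_surfaces = SurfaceSets(
        sup_nodes, inf_nodes,
        np.asarray(sup_outer) + shift, np.asarray(inf_outer) + shift,
    )
    return capped, new_surfaces


def save_mesh(mesh: VoxelMesh, path) -> None:
    """Write a mesh as a portable JSON container."""
    import json
    from pathlib import Path

    payload = {
        "voxel_size": mesh.voxel_size,
        "origin": list(mesh.origin),
        "voxels": mesh.voxels.tolist(),
        "node_coords": mesh.node_coords.tolist(),
        "element_nodes": mesh.element_nodes.tolist(),
        "element_density": mesh.element_density.tolist(),
        "pmma_elements": mesh.pmma_elements.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_mesh(path) -> VoxelMesh:
    import json
    from pathlib import Path

    raw = json.loads(Path(path).read_text())
    return VoxelMesh(
        voxels=np.asarray(raw["voxels"], dtype=np.int64),
        node_coords=np.asarray(raw["node_coords"], dtype=float),
        element_nodes=np.asarray(raw["element_nodes"], dtype=np.int64),
        element_density=np.asarray(raw["element_density"], dtype=float),
        voxel_size=float(raw["voxel_size"]),
        origin=tuple(raw["origin"]),
        pmma_elements=np.asarray(raw["pmma_elements"], dtype=bool),
    )


def segment_cortical(density: Volume, mask: Volume,
                     threshold: float = 1.0, layer_mm: float = 2.0) -> Volume:
    """Cortical-bone mask: in-mask voxels denser than ``threshold`` g/cm³
    plus the ``layer_mm``-thick inward surface layer of the mask."""
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    dense = m & (density.data > threshold)
    edt = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    layer = m & (edt <= layer_mm)
    out = mask.copy_with((dense | layer).astype(np.uint8))
    return out
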
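import numpy as np
import pytest

from spinefe import mesh as mesh_mod
from spinefe import synthgen
from spinefe.volume import Volume

from conftest import make_column_mesh


def box_volumes(nx, ny, nz, rho=0.2, spacing=1.0):
    dens = Volume(np.full((nx, ny, nz), rho), (spacing,) * 3)
    mask = Volume(np.ones((nx, ny, nz), dtype=np.int32), (spacing,) * 3)
    return dens, mask


def test_build_mesh_counts_and_shared_nodes():
    mesh = make_column_mesh(3, 4, 5)
    assert mesh.n_elements == 3 * 4 * 5
    assert mesh.n_nodes == 4 * 5 * 6
    # connectivity is right-handed HEX8: positive volume via scalar triple product
    n0 = mesh.node_coords[mesh.element_nodes[:, 0]]
    ex = mesh.node_coords[mesh.element_nodes[:, 1]] - n0
    ey = mesh.node_coords[mesh.element_nodes[:, 3]] - n0
    ez = mesh.node_coords[mesh.element_nodes[:, 4]] - n0
    vol = np.einsum("ij,ij->i", np.cross(ex, ey), ez)
    assert np.all(vol > 0)


def test_build_mesh_keeps_largest_component_and_floors_density():
    dens = np.full((10, 3, 3), 0.2)
    dens[0, 0, 0] = -0.5                      # negative after calibration
    mask = np.zeros((10, 3, 3), dtype=np.int32)
    mask[:4] = 1                              # 4x3x3 component (largest)
    mask[6:8, :2, :2] = 1                     # small detached component
    m = mesh_mod.build_mesh(Volume(dens), Volume(mask))
    assert m.n_elements == 4 * 3 * 3
    assert np.all(m.voxels[:, 0] < 4)
    assert m.element_density.min() >= mesh_mod.DENSITY_FLOOR


def test_build_mesh_rejects_empty_and_mismatched():
    with pytest.raises(ValueError):
        mesh_mod.build_mesh(Volume(np.zeros((3, 3, 3))),
                            Volume(np.zeros((3, 3, 3), dtype=np.int32)))
    with pytest.raises(ValueError):
        mesh_mod.build_mesh(Volume(np.zeros((3, 3, 3))),
                            Volume(np.ones((4, 3, 3), dtype=np.int32)))


def test_resample_isotropic_scalar_and_label():
    data = np.linspace(0, 1, 4 * 4 * 8).reshape(4, 4, 8)
    vol = Volume(data, (2.0, 2.0, 1.0))
    out = mesh_mod.resample_isotropic(vol, 1.0)
    assert out.spacing == (1.0, 1.0, 1.0)
    assert out.shape == (8, 8, 8)
    lab = Volume((data > 0.5).astype(np.int32), (2.0, 2.0, 1.0))
    out_l = mesh_mod.resample_isotropic(lab, 1.0)
    assert out_l.data.dtype == lab.data.dtype
    assert set(np.unique(out_l.data)) <= {0, 1}


def test_resample_isotropic_identity_short_circuit():
    vol = Volume(np.random.default_rng(0).normal(size=(4, 4, 4)), (1.0, 1.0, 1.0))
    out = mesh_mod.resample_isotropic(vol, 1.0)
    assert np.array_equal(out.data, vol.data)


def test_find_endplate_surfaces_flat_column():
    mesh = make_column_mesh(6, 6, 8)
    s = mesh_mod.find_endplate_surfaces(mesh)
    # flat caps: full footprint participates
    assert len(s.superior_voxels) == 36
    assert len(s.inferior_voxels) == 36
    assert np.all(s.superior_voxels[:, 2] == 7)
    assert np.all(s.inferior_voxels[:, 2] == 0)
    assert len(s.superior_nodes) == 49
    assert len(np.intersect1d(s.superior_nodes, s.inferior_nodes)) == 0


def test_find_endplate_surfaces_excludes_dome():
    # column with a one-voxel bump on top: the bump has no 5-deep backing run
    # only in the off-extreme columns, so only the bump column is superior
    dens = np.full((5, 5, 9), 0.2)
    mask = np.zeros((5, 5, 9), dtype=np.int32)
    mask[:, :, :8] = 1
    mask[2, 2, 8] = 1   # single-voxel dome apex
    m = mesh_mod.build_mesh(Volume(dens), Volume(mask))
    s = mesh_mod.find_endplate_surfaces(m)
    # apex is the extreme plane and is backed by a full in-column run
    assert len(s.superior_voxels) == 1
    assert tuple(s.superior_voxels[0]) == (2, 2, 8)
    # inferior face is flat and complete
    assert len(s.inferior_voxels) == 25


def test_find_endplate_surfaces_needs_z_span():
    mesh = make_column_mesh(6, 6, 3)
    with pytest.raises(ValueError):
        mesh_mod.find_endplate_surfaces(mesh)


def test_add_pmma_caps_geometry_and_materials():
    mesh = make_column_mesh(4, 4, 6)
    s = mesh_mod.find_endplate_surfaces(mesh)
    capped, cs = mesh_mod.add_pmma_caps(mesh, s, thickness_voxels=3)
    assert capped.n_elements == mesh.n_elements + 2 * 3 * 16
    assert capped.pmma_elements.sum() == 2 * 3 * 16
    assert capped.voxels.min() >= 0
    # total height grows by twice the cap thickness
    assert np.isclose(capped.z_extent_mm(), mesh.z_extent_mm() + 6.0)
    assert np.isclose(capped.z_extent_mm(include_pmma=False), mesh.z_extent_mm())
    # new surfaces live on the outer cap faces
    assert np.all(cs.superior_voxels[:, 2] == capped.voxels[:, 2].max())
    assert np.all(cs.inferior_voxels[:, 2] == 0)


def test_add_pmma_caps_zero_thickness_noop():
    mesh = make_column_mesh(4, 4, 6)
    s = mesh_mod.find_endplate_surfaces(mesh)
    capped, cs = mesh_mod.add_pmma_caps(mesh, s, thickness_voxels=0)
    assert capped is mesh and cs is s
    with pytest.raises(ValueError):
        mesh_mod.add_pmma_caps(mesh, s, thickness_voxels=-1)


def test_mesh_save_load_roundtrip(tmp_path):
    mesh = make_column_mesh(3, 3, 5)
    p = tmp_path / "mesh.json"
    mesh_mod.save_mesh(mesh, p)
    back = mesh_mod.load_mesh(p)
    assert np.array_equal(back.voxels, mesh.voxels)
    assert np.allclose(back.node_coords, mesh.node_coords)
    assert np.array_equal(back.element_nodes, mesh.element_nodes)
    assert np.allclose(back.element_density, mesh.element_density)
    assert back.voxel_size == mesh.voxel_size


def test_align_to_reference_recovers_translation():
    base = np.zeros((24, 24, 24), dtype=np.int32)
    base[4:12, 6:12, 4:20] = 1
    moved = np.zeros((24, 24, 24), dtype=np.int32)
    moved[8:16, 10:16, 4:20] = 1  # +4 in x, +4 in y
    t = mesh_mod.align_to_reference(Volume(moved), Volume(base), icp_iterations=5)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
    assert np.allclose(t.translation, [-4.0, -4.0, 0.0], atol=1e-6)
    assert np.allclose(t.pc_scale, 1.0, atol=1e-9)
    assert t.residual_mm < 1e-6


def test_align_to_reference_scale_factors():
    base = np.zeros((30, 30, 30), dtype=np.int32)
    base[5:25, 10:20, 10:20] = 1
    small = np.zeros((30, 30, 30), dtype=np.int32)
    small[10:20, 12:18, 12:18] = 1
    t = mesh_mod.align_to_reference(Volume(small), Volume(base))
    assert np.all(t.pc_scale > 1.0)  # reference is larger along every axis


def test_segment_cortical_shell_and_dense():
    truth = synthgen.GroundTruth()
    geom = synthgen.VertebraGeometry(body_halfwidths=(8.0, 7.0), body_height=10.0,
                                     shell_thickness=1.5, shell_density=1.2)
    hu, labels, dens = synthgen.make_vertebra(geom, truth)
    dens_vol = hu.copy_with(dens)
    cortical = mesh_mod.segment_cortical(dens_vol, labels, threshold=1.0, layer_mm=2.0)
    body = labels.data.astype(bool)
    cort = cortical.data.astype(bool)
    assert cort.any()
    assert np.all(body[cort])              # cortical is inside the body
    assert np.all(cort[body & (dens > 1.0)])  # all dense voxels captured
    assert not cort.all()
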
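import json

import numpy as np
import pytest

from spinefe import calibration as cal
from spinefe import synthgen
from spinefe.levels_order import level_index
from spinefe.volume import read_volume


def test_ground_truth_roundtrip():
    t = synthgen.GroundTruth(slope_true=0.8, intercept_true=-5.0)
    rho = np.array([-80.0, 20.0, 40.0, 300.0])
    hu = t.density_to_hu(rho)
    assert np.allclose(0.8 * hu - 5.0, rho)
    with pytest.raises(ValueError):
        synthgen.GroundTruth(slope_true=0.0)


def test_make_hu_volume_labels_and_hu_values():
    t = synthgen.GroundTruth()
    hu, labels = synthgen.make_hu_volume(t)
    assert hu.shape == labels.shape == synthgen.DEFAULT_TISSUE_SHAPE
    for code, name in synthgen.TISSUE_LABELS.items():
        region = labels.data == code
        assert region.any()
        if name == "air":
            assert np.all(hu.data[region] >= cal.AIR_HU_RANGE[0])
            assert np.all(hu.data[region] <= cal.AIR_HU_RANGE[1])
        else:
            expected = t.density_to_hu(synthgen.ASSUMED_TISSUE_DENSITIES[name])
            assert np.allclose(hu.data[region], expected)
    # unlabelled background sits at water
    assert np.all(hu.data[labels.data == 0] == 0.0)


def test_make_hu_volume_rejects_overlap():
    layout = dict(synthgen.DEFAULT_TISSUE_LAYOUT)
    layout["fat"] = layout["blood"]
    with pytest.raises(ValueError):
        synthgen.make_hu_volume(synthgen.GroundTruth(), tissue_layout=layout)


def test_embed_phantom_rods_disjoint_from_tissues():
    t = synthgen.GroundTruth()
    hu, labels = synthgen.make_hu_volume(t)
    hu2, rods = synthgen.embed_phantom(hu, t)
    assert set(np.unique(rods.data)) == {0, 1, 2, 3, 4, 5}
    overlap = (rods.data > 0) & (labels.data > 0)
    assert overlap.sum() == 0
    # rod HU follow the truth line
    for i, dens in enumerate(cal.PhantomSpec().rod_densities, start=1):
        assert np.allclose(hu2.data[rods.data == i], t.density_to_hu(dens))


def test_make_vertebra_structure():
    t = synthgen.GroundTruth()
    geom = synthgen.VertebraGeometry(body_halfwidths=(8.0, 6.0), body_height=10.0,
                                     shell_thickness=1.0, shell_density=1.0,
                                     trabecular_density_mean=0.15,
                                     trabecular_density_sd=0.02)
    hu, labels, dens = synthgen.make_vertebra(geom, t, seed=3)
    body = labels.data == 1
    assert body.any()
    # shell voxels at shell density, interior near the trabecular mean
    assert np.isclose(dens[body].max(), 1.0)
    interior = body & (dens < 0.9)
    assert interior.any()
    assert abs(dens[interior].mean() - 0.15) < 0.05
    # HU invert the truth line exactly at zero noise
    assert np.allclose(0.85 * hu.data[body] - 4.0, dens[body] * 1000.0)
    assert np.all(hu.data[~body] == -1000.0)


def test_make_vertebra_weakened_band():
    t = synthgen.GroundTruth()
    base = dict(body_halfwidths=(8.0, 6.0), body_height=12.0,
                shell_thickness=1.0, shell_density=1.0,
                trabecular_density_mean=0.2, trabecular_density_sd=0.0)
    g0 = synthgen.VertebraGeometry(**base)
    g1 = synthgen.VertebraGeometry(**base, weakened_band=((4.0, 8.0), 0.5))
    _, _, d0 = synthgen.make_vertebra(g0, t, seed=1)
    _, _, d1 = synthgen.make_vertebra(g1, t, seed=1)
    changed = d1 < d0
    assert changed.any()
    assert np.allclose(d1[changed], 0.5 * d0[changed])
    # band only affects the interior mid-body
    zs = np.nonzero(changed.any(axis=(0, 1)))[0]
    assert zs.min() >= 3 and zs.max() <= 3 + 8


def test_geometry_validation():
    with pytest.raises(ValueError):
        synthgen.VertebraGeometry(body_halfwidths=(0.0, 5.0))
    with pytest.raises(ValueError):
        synthgen.VertebraGeometry(shell_thickness=20.0)
    with pytest.raises(ValueError):
        synthgen.VertebraGeometry(weakened_band=((2.0, 4.0), 1.5))


def test_geometry_scaled_preserves_area_ratio():
    g = synthgen.VertebraGeometry()
    g2 = g.scaled(1.21)
    a0 = g.body_halfwidths[0] * g.body_halfwidths[1]
    a2 = g2.body_halfwidths[0] * g2.body_halfwidths[1]
    assert np.isclose(a2 / a0, 1.21)


def test_default_ratio_profile():
    prof = synthgen.default_ratio_profile(("T12", "L1", "L2"), per_level=1.06)
    assert np.isclose(prof["L1"], 1.0)
    assert np.isclose(prof["L2"], 1.06)
    assert np.isclose(prof["T12"], 1 / 1.06)


def test_make_cohort_structure_and_truth():
    subs, truth = synthgen.make_cohort(3, levels=("T12", "L1", "L2"),
                                       base_geometry=synthgen.VertebraGeometry(
                                           body_halfwidths=(6.0, 5.0),
                                           body_height=8.0, shell_thickness=1.0),
                                       seed=5)
    assert len(subs) == 3
    for s in subs:
        assert set(s.vertebrae) == {"T12", "L1", "L2"}
        assert s.sex in ("M", "F")
        assert truth.sex[s.subject_id] == s.sex
    assert np.isclose(truth.level_strength_ratio_true[("T12", "L1")], 1 / 1.06)
    assert np.isclose(truth.level_strength_ratio_true[("L1", "L2")], 1 / 1.06)
    # cross-sectional areas scale with the profile within a subject
    s0 = subs[0]
    n_l2 = (s0.vertebrae["L2"].labels.data == 1).sum()
    n_l1 = (s0.vertebrae["L1"].labels.data == 1).sum()
    assert n_l2 > n_l1


def test_make_cohort_fractures_deterministic_per_seed():
    a, ta = synthgen.make_cohort(4, levels=("L1", "L2"), fracture_rate=0.5,
                                 base_geometry=synthgen.VertebraGeometry(
                                     body_halfwidths=(6.0, 5.0),
                                     body_height=8.0, shell_thickness=1.0),
                                 seed=9)
    b, tb = synthgen.make_cohort(4, levels=("L1", "L2"), fracture_rate=0.5,
                                 base_geometry=synthgen.VertebraGeometry(
                                     body_halfwidths=(6.0, 5.0),
                                     body_height=8.0, shell_thickness=1.0),
                                 seed=9)
    assert ta.fracture_flags == tb.fracture_flags
    assert any(ta.fracture_flags.values()) or len(ta.fracture_flags) == 8


def test_write_subject_files(tmp_path):
    subs, truth = synthgen.make_cohort(1, levels=("L1",),
                                       base_geometry=synthgen.VertebraGeometry(
                                           body_halfwidths=(6.0, 5.0),
                                           body_height=8.0, shell_thickness=1.0),
                                       seed=0)
    synthgen.write_subject(subs[0], tmp_path, truth)
    sdir = tmp_path / subs[0].subject_id
    hu = read_volume(sdir / "L1_hu.nii.gz")
    labels = read_volume(sdir / "L1_labels.nii.gz", label=True)
    assert np.allclose(hu.data, subs[0].vertebrae["L1"].hu.data)
    assert np.array_equal(labels.data, subs[0].vertebrae["L1"].labels.data)
    sidecar = json.loads((sdir / "truth.json").read_text())
    assert sidecar["slope_true"] == truth.slope_true
    assert "L1" in sidecar["levels"]


def test_level_index_ordering():
    assert level_index("L1") == level_index("T12") + 1
    assert level_index("L2") > level_index("T11")
    with pytest.raises(ValueError):
        level_index("C7")
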
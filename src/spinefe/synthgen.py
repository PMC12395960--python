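"""Synthetic CT phantoms with known ground truth.

Everything downstream — calibration, meshing, FE simulation, level
normalization — is exercised on volumes produced here, where the HU->density
line, the voxel density field, per-level strength ratios, and fracture flags
are all known exactly.

The forward model inverts the calibration line: a voxel with true
K2HPO4-equivalent density rho (mg/cm³) is written as
``HU = (rho - intercept_true) / slope_true`` plus optional additive Gaussian
HU noise.  Air is written as measured HU near -1000 (it does not lie on the
tissue line) so the air-QC path behaves as on real scans.

Vertebral phantoms are elliptic cylinders with a dense cortical shell, flat
endplates, a smoothly heterogeneous trabecular interior, and an optional
locally weakened band emulating a fractured vertebra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calibration import AIR_HU_RANGE, PhantomSpec, erode_ball
from .levels_order import LEVEL_ORDER, level_index
from .volume import Volume, write_volume

__all__ = [
    "GroundTruth",
    "VertebraGeometry",
    "SubjectData",
    "VertebraData",
    "ASSUMED_TISSUE_DENSITIES",
    "DEFAULT_TISSUE_LAYOUT",
    "default_ratio_profile",
    "make_hu_volume",
    "embed_phantom",
    "make_vertebra",
    "make_cohort",
    "write_subject",
]

#: Assumed K2HPO4-equivalent densities (mg/cm³) of the reference tissues.
#: Air is not on the tissue line; it is handled as measured HU and used for
#: quality control only (optionally includable in the fit).
ASSUMED_TISSUE_DENSITIES = {
    "fat": -80.0,
    "blood": 20.0,
    "muscle": 40.0,
    "bone": 300.0,
}

#: Integer label codes for the reference-tissue masks.
TISSUE_LABELS = {1: "air", 2: "fat", 3: "blood", 4: "muscle", 5: "bone"}

#: Default reference-tissue layout: disjoint cubic regions, each 14 voxels
#: across so a 5-voxel ball erosion leaves a 4x4x4 core (>= 20 voxels).
DEFAULT_TISSUE_LAYOUT = {
    "air": ((2, 16), (2, 16), (24, 38)),
    "fat": ((2, 16), (2, 16), (2, 16)),
    "blood": ((2, 16), (20, 34), (2, 16)),
    "muscle": ((20, 34), (2, 16), (2, 16)),
    "bone": ((20, 34), (20, 34), (2, 16)),
}
DEFAULT_TISSUE_SHAPE = (40, 40, 58)  # slices above z=38 left free for a phantom


@dataclass
class GroundTruth:
    """Known truth behind one synthetic scan or cohort."""

    slope_true: float = 0.85          # mg/cm³ per HU
    intercept_true: float = -4.0      # mg/cm³
    level_strength_ratio_true: dict = field(default_factory=dict)  # adjacent-pair ratios
    fracture_flags: dict = field(default_factory=dict)             # (subject, level) -> bool
    sex: dict = field(default_factory=dict)                        # subject -> "M"/"F"

    def __post_init__(self):
        if self.slope_true <= 0:
            raise ValueError("calibration slope must be positive")
        for pair, r in self.level_strength_ratio_true.items():
            if r <= 0:
                raise ValueError(f"nonpositive strength ratio for {pair}")

    def density_to_hu(self, density_mg: np.ndarray) -> np.ndarray:
        """Invert the calibration line (densities in mg/cm³)."""
        return (np.asarray(density_mg, dtype=float) - self.intercept_true) / self.slope_true


@dataclass
class VertebraGeometry:
    """Elliptic-cylinder vertebral-body phantom parameters (mm, g/cm³)."""

    body_halfwidths: tuple = (17.0, 14.0)   # (x, y) mm
    body_height: float = 27.0               # z, mm
    shell_thickness: float = 1.5            # mm
    shell_density: float = 1.2              # g/cm³
    trabecular_density_mean: float = 0.15   # g/cm³
    trabecular_density_sd: float = 0.03     # g/cm³
    weakened_band: tuple | None = None      # ((z0_mm, z1_mm), multiplier)

    def __post_init__(self):
        if min(self.body_halfwidths) <= 0 or self.body_height <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.shell_thickness <= 0 or self.shell_thickness >= min(self.body_halfwidths):
            raise ValueError("shell thickness must be positive and smaller than the body")
        if self.weakened_band is not None:
            (_z0, _z1), mult = self.weakened_band
            if not (0 < mult <= 1):
                raise ValueError("weakened-band density multiplier must be in (0, 1]")

    def scaled(self, area_factor: float) -> "VertebraGeometry":
        """Scale the cross-sectional area by ``area_factor`` (halfwidths by its sqrt)."""
        s = float(np.sqrt(area_factor))
        return VertebraGeometry(
            (self.body_halfwidths[0] * s, self.body_halfwidths[1] * s),
            self.body_height, self.shell_thickness, self.shell_density,
            self.trabecular_density_mean, self.trabecular_density_sd,
            self.weakened_band,
        )


@dataclass
class VertebraData:
    level: str
    hu: Volume
    labels: Volume
    density_true: np.ndarray      # g/cm³ per voxel (0 outside the body)
    geometry: VertebraGeometry
    fractured: bool = False


@dataclass
class SubjectData:
    subject_id: str
    sex: str
    vertebrae: dict               # level -> VertebraData


def _check_layout(layout: dict, shape: tuple) -> None:
    grid = np.zeros(shape, dtype=np.int16)
    for name, box in layout.items():
        (x0, x1), (y0, y1), (z0, z1) = box
        if x1 > shape[0] or y1 > shape[1] or z1 > shape[2] or min(x0, y0, z0) < 0:
            raise ValueError(f"region '{name}' exceeds the volume bounds")
        grid[x0:x1, y0:y1, z0:z1] += 1
    if (grid > 1).any():
        raise ValueError("tissue layout regions overlap")


def make_hu_volume(truth: GroundTruth, tissue_layout: dict | None = None,
                   noise_sd: float = 0.0, seed: int = 0,
                   shape: tuple | None = None,
                   spacing: float = 1.0) -> tuple[Volume, Volume]:
    """Synthetic reference-tissue scan: HU volume plus tissue label mask.

    Each labelled tissue region is written at the HU its assumed density
    maps to under the inverse of the truth line; air is written as measured
    HU around -1000 (clipped into the air QC window); the unlabelled
    background sits at water (0 HU).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    layout = dict(tissue_layout) if tissue_layout is not None else dict(DEFAULT_TISSUE_LAYOUT)
    shape = tuple(shape) if shape is not None else (
        DEFAULT_TISSUE_SHAPE if tissue_layout is None else None)
    if shape is None:
        hi = np.array([[b[0][1], b[1][1], b[2][1]] for b in layout.values()]).max(axis=0)
        shape = tuple(int(v) + 2 for v in hi)
    _check_layout(layout, shape)

    rng = np.random.default_rng(seed)
    hu = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    name_to_code = {v: k for k, v in TISSUE_LABELS.items()}

    for name, box in layout.items():
        (x0, x1), (y0, y1), (z0, z1) = box
        region = (slice(x0, x1), slice(y0, y1), slice(z0, z1))
        n = (x1 - x0) * (y1 - y0) * (z1 - z0)
        noise = rng.normal(0.0, noise_sd, size=(x1 - x0, y1 - y0, z1 - z0)) if noise_sd else 0.0
        if name == "air":
            base = -1000.0
            vals = np.clip(base + noise, AIR_HU_RANGE[0] + 1, AIR_HU_RANGE[1] - 1)
        else:
            base = truth.density_to_hu(ASSUMED_TISSUE_DENSITIES[name])
            vals = base + noise
        hu[region] = vals
        labels[region] = name_to_code[name]
        core = erode_ball(labels == name_to_code[name], 5)
        if core.sum() < 20:
            raise ValueError(
                f"region '{name}' ({n} voxels) too small to survive a 5-voxel erosion"
            )
    sp = (spacing,) * 3
    return Volume(hu, sp), Volume(labels, sp)


def embed_phantom(hu: Volume, truth: GroundTruth, spec: PhantomSpec | None = None,
                  noise_sd: float = 0.0, seed: int = 0) -> tuple[Volume, Volume]:
    """Stamp a 5-rod calibration phantom into a scan.

    Rods are y-axis cylinders evenly spaced along x near the inferior edge
    of the volume; their HU follow the same truth line as the tissues.
    Returns the modified HU volume and a rod label volume (codes 1..5).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    data = hu.data.copy()
    rods = np.zeros(hu.shape, dtype=np.int32)
    sx = hu.spacing[0]
    r_vox = spec.rod_radius / sx
    nx, ny, nz = hu.shape
    # shrink spacing and radius together if the field of view is narrow
    spacing_vox = min(spec.rod_spacing / sx, (nx - 2.0) / 4.6)
    r_vox = min(r_vox, spacing_vox / 2.0 - 0.6)
    if r_vox < 1.0:
        raise ValueError("volume too narrow to embed a 5-rod phantom")
    zc = nz - int(round(r_vox)) - 2
    x0 = nx / 2 - 2 * spacing_vox
    xx, zz = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
    for i, dens in enumerate(spec.rod_densities, start=1):
        xc = x0 + (i - 1) * spacing_vox
        disk = (xx - xc) ** 2 + (zz - zc) ** 2 <= r_vox**2
        if not disk.any():
            continue
        base = truth.density_to_hu(dens)
        for y in range(1, ny - 1):
            sl = rods[:, y, :]
            sl[disk] = i
            vals = base + (rng.normal(0.0, noise_sd, size=int(disk.sum())) if noise_sd else 0.0)
            plane = data[:, y, :]
            plane[disk] = vals
    return Volume(data, hu.spacing, hu.origin), Volume(rods, hu.spacing, hu.origin)


def make_vertebra(geom: VertebraGeometry, truth: GroundTruth, spacing: float = 1.0,
                  noise_sd: float = 0.0, seed: int = 0,
                  margin_voxels: int = 3) -> tuple[Volume, Volume, np.ndarray]:
    """Voxelized vertebral-body phantom.

    Returns (HU volume, body label mask, true density field in g/cm³).
    The body is an elliptic cylinder with flat endplates; the outer
    ``shell_thickness`` is cortical (``shell_density``), the interior is a
    smooth Gaussian random field around the trabecular mean, and an
    optional weakened band multiplies interior density over a z-range.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ax, ay = geom.body_halfwidths
    nx = int(np.ceil(2 * ax / spacing)) + 2 * margin_voxels
    ny = int(np.ceil(2 * ay / spacing)) + 2 * margin_voxels
    nzb = int(np.ceil(geom.body_height / spacing))
    nz = nzb + 2 * margin_voxels
    if nx < 4 or ny < 4 or nzb < 1:
        raise ValueError("geometry too small for the requested spacing")

    # voxel-centre coordinates in mm, body centred in-plane
    x = (np.arange(nx) + 0.5) * spacing - nx * spacing / 2
    y = (np.arange(ny) + 0.5) * spacing - ny * spacing / 2
    xx, yy = np.meshgrid(x, y, indexing="ij")
    inside2d = (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0
    interior2d = (xx / (ax - geom.shell_thickness)) ** 2 + (
        yy / (ay - geom.shell_thickness)) ** 2 <= 1.0

    z0, z1 = margin_voxels, margin_voxels + nzb
    shell_vox = max(int(round(geom.shell_thickness / spacing)), 1)

    mask = np.zeros((nx, ny, nz), dtype=bool)
    mask[:, :, z0:z1] = inside2d[:, :, None]

    interior = np.zeros_like(mask)
    interior[:, :, z0 + shell_vox:z1 - shell_vox] = interior2d[:, :, None]
    interior &= mask

    rng = np.random.default_rng(seed)
    density = np.zeros((nx, ny, nz), dtype=float)   # g/cm³
    density[mask] = geom.shell_density
    if geom.trabecular_density_sd > 0:
        noise = rng.standard_normal(size=(nx, ny, nz))
        noise = ndimage.gaussian_filter(noise, sigma=1.5)
        noise *= geom.trabecular_density_sd / max(noise.std(), 1e-12)
    else:
        noise = np.zeros((nx, ny, nz))
    trab = geom.trabecular_density_mean + noise
    density[interior] = np.maximum(trab[interior], 0.01)

    if geom.weakened_band is not None:
        (zb0, zb1), mult = geom.weakened_band
        k0 = z0 + int(np.floor(zb0 / spacing))
        k1 = z0 + int(np.ceil(zb1 / spacing))
        band = np.zeros_like(mask)
        band[:, :, max(k0, 0):min(k1, nz)] = True
        density[band & interior] *= mult

    hu = np.full((nx, ny, nz), -1000.0)
    body = mask
    hu[body] = truth.density_to_hu(density[body] * 1000.0)
    if noise_sd > 0:
        hu[body] += rng.normal(0.0, noise_sd, size=int(body.sum()))
        out = ~body
        hu[out] = np.clip(hu[out] + rng.normal(0.0, noise_sd, size=int(out.sum())),
                          AIR_HU_RANGE[0] + 1, AIR_HU_RANGE[1] - 1)

    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    labels[body] = 1
    sp = (spacing,) * 3
    return Volume(hu, sp), Volume(labels, sp), density


def default_ratio_profile(levels=LEVEL_ORDER, per_level: float = 1.06) -> dict:
    """Cross-sectional-area multipliers relative to L1: strength (and area)
    grow ``per_level``-fold per level moving caudally."""
    i_l1 = level_index("L1")
    return {lv: per_level ** (level_index(lv) - i_l1) for lv in levels}


def make_cohort(n_subjects: int, levels=("T11", "T12", "L1", "L2", "L3"),
                ratio_profile: dict | None = None, fracture_rate: float = 0.0,
                base_geometry: VertebraGeometry | None = None,
                noise_sd: float = 0.0, density_range: tuple = (0.10, 0.25),
                fracture_multiplier: float = 0.6,
                spacing: float = 1.0, seed: int = 0) -> tuple[list[SubjectData], GroundTruth]:
    """Multi-level synthetic cohort with known level-strength structure.

    Per subject, every requested level shares one trabecular density (drawn
    uniformly from ``density_range``) and one base geometry; the level's
    cross-sectional area is scaled by ``ratio_profile`` so that, for
    homogeneous columns, the true adjacent-level strength ratio equals the
    area ratio.  Fractured vertebrae (drawn independently at
    ``fracture_rate``) get a mid-body weakened band.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    levels = list(levels)
    if not levels:
        raise ValueError("empty level list")
    for lv in levels:
        level_index(lv)
    profile = ratio_profile if ratio_profile is not None else default_ratio_profile(levels)
    if any(m <= 0 for m in profile.values()):
        raise ValueError("ratio multipliers must be positive")
    geom0 = base_geometry or VertebraGeometry()

    rng = np.random.default_rng(seed)
    ordered = sorted(set(levels), key=level_index)
    # keyed (upper, lower) as S_upper / S_lower, matching the level graph
    adj_ratios = {
        (a, b): profile[a] / profile[b]
        for a, b in zip(ordered, ordered[1:])
        if level_index(b) == level_index(a) + 1
    }
    truth = GroundTruth(level_strength_ratio_true=adj_ratios)

    subjects = []
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        truth.sex[sid] = sex
        rho = float(rng.uniform(*density_range))
        vertebrae = {}
        for lv in levels:
            fractured = bool(rng.random() < fracture_rate)
            truth.fracture_flags[(sid, lv)] = fractured
            band = None
            if fractured:
                h = geom0.body_height
                band = ((h / 3, 2 * h / 3), fracture_multiplier)
            geom = VertebraGeometry(
                geom0.body_halfwidths, geom0.body_height, geom0.shell_thickness,
                geom0.shell_density, rho, geom0.trabecular_density_sd, band,
            ).scaled(profile[lv])
            vseed = int(rng.integers(0, 2**31 - 1))
            hu, labels, dens = make_vertebra(geom, truth, spacing=spacing,
                                             noise_sd=noise_sd, seed=vseed)
            vertebrae[lv] = VertebraData(lv, hu, labels, dens, geom, fractured)
        subjects.append(SubjectData(sid, sex, vertebrae))
    return subjects, truth


def write_subject(subject: SubjectData, out_dir: str | Path,
                  truth: GroundTruth | None = None) -> None:
    """Write one subject as paired NIfTI volumes plus a JSON truth sidecar."""
    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"subject_id": subject.subject_id, "sex": subject.sex, "levels": {}}
    for lv, v in subject.vertebrae.items():
        write_volume(v.hu, out / f"{lv}_hu.nii.gz")
        write_volume(v.labels, out / f"{lv}_labels.nii.gz")
        sidecar["levels"][lv] = {
            "fractured": v.fractured,
            "geometry": asdict(v.geometry),
        }
    if truth is not None:
        sidecar["slope_true"] = truth.slope_true
        sidecar["intercept_true"] = truth.intercept_true
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2, default=str))
    (Path(out_dir) / "label_codes.json").write_text(
        json.dumps({"body": 1, "tissues": TISSUE_LABELS}, indent=2))
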
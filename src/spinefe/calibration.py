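"""HU-to-density calibration: phantomless (tissue references) and 5-rod phantom.

A scan-specific affine line ``density = slope * HU + intercept`` (mg/cm³
K2HPO4 per HU) is fit by ordinary least squares from either internal
reference tissues (fat, muscle, blood, bone) or the rods of an in-scan
calibration phantom.  Air is thresholded between -1050 and -950 HU and, by
default, used only as a quality check on the scan rather than as a fit
point.  All region statistics are taken after a morphological erosion (3-D
ball, radius in voxels) to suppress partial-volume voxels at region
boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .volume import Volume

__all__ = [
    "TissueSample",
    "CalibrationLine",
    "AgreementReport",
    "PhantomSpec",
    "erode_ball",
    "segment_air",
    "extract_tissue_hu",
    "fit_phantomless",
    "fit_phantom",
    "apply_calibration",
    "measure_vbmd",
    "compare_calibrations",
    "AIR_HU_RANGE",
]

#: HU window used to threshold background air.
AIR_HU_RANGE = (-1050.0, -950.0)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class SingularFitError(ValueError):
    """All reference points share one HU value; the line is undetermined."""


class RegionErodedAwayError(ValueError):
    """A reference region vanished under the requested erosion."""


class PartialPhantomError(ValueError):
    """One or more phantom rods are absent from the label volume."""


@dataclass
class TissueSample:
    """Mean HU of one eroded reference region with its assumed density."""

    label: str
    mean_hu: float
    n_voxels: int
    assumed_density: float       # mg/cm³ K2HPO4

    def __post_init__(self):
        if self.n_voxels <= 0:
            raise ValueError(f"region '{self.label}' has no voxels")


@dataclass
class CalibrationLine:
    """Affine HU -> K2HPO4 density map with fit diagnostics."""

    slope: float                 # mg/cm³ per HU
    intercept: float             # mg/cm³
    r2: float
    source: str                  # phantomless | phantom
    n_points: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationLine":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PhantomSpec:
    """Geometry and nominal densities of a 5-rod calibration phantom."""

    rod_densities: tuple = (-51.8, -3.6, 58.9, 157.0, 375.8)  # mg/cm³ K2HPO4
    rod_radius: float = 6.0       # mm
    rod_spacing: float = 16.0     # mm, centre-to-centre along x

    def __post_init__(self):
        d = tuple(float(v) for v in self.rod_densities)
        if len(d) != 5:
            raise ValueError("phantom must have exactly 5 rods")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("rod densities must be strictly increasing")
        if d[0] < -60 or d[-1] > 400:
            raise ValueError("rod densities outside the plausible [-60, 400] range")
        self.rod_densities = d


@dataclass
class AgreementReport:
    """Pearson correlation plus Bland-Altman statistics for paired values."""

    pearson_r: float
    mean_difference: float       # mean(a - b)
    loa_lower: float             # mean - 1.96 SD
    loa_upper: float             # mean + 1.96 SD
    n: int
    degenerate: bool = False     # zero variance: r undefined


def erode_ball(mask: np.ndarray, radius_voxels: float) -> np.ndarray:
    """Erode a binary mask by a ball of the given radius (in voxels).

    Implemented as a Euclidean distance-transform threshold, which is exact
    for ball structuring elements and much faster than voxel-wise
    morphology for large radii.
    """
    if radius_voxels <= 0:
        return mask.astype(bool)
    edt = ndimage.distance_transform_edt(mask)
    return edt > radius_voxels


def segment_air(hu: Volume) -> np.ndarray:
    """Background-air mask: HU threshold then largest 6-connected component."""
    lo, hi = AIR_HU_RANGE
    cand = (hu.data >= lo) & (hu.data <= hi)
    if not cand.any():
        raise ValueError(f"no voxels in the air HU window [{lo}, {hi}]")
    labels, n = ndimage.label(cand, structure=_FACE_STRUCT)
    if n == 1:
        return cand
    counts = np.bincount(labels.ravel())[1:]
    return labels == (np.argmax(counts) + 1)


def extract_tissue_hu(hu: Volume, labels: Volume, assumed_densities: dict,
                      label_names: dict, erosion_voxels: int = 5) -> list[TissueSample]:
    """Per-tissue mean HU over 5-voxel-eroded labelled regions.

    ``label_names`` maps integer label -> tissue name; ``assumed_densities``
    maps tissue name -> assumed K2HPO4-equivalent density (mg/cm³).  A
    region that vanishes under erosion raises, naming the region.
    """
    samples = []
    for code, name in sorted(label_names.items()):
        if name not in assumed_densities:
            continue
        region = labels.data == code
        if not region.any():
            raise ValueError(f"label {code} ('{name}') absent from the label volume")
        eroded = erode_ball(region, erosion_voxels)
        n = int(eroded.sum())
        if n == 0:
            raise RegionErodedAwayError(
                f"region '{name}' vanished under a {erosion_voxels}-voxel erosion"
            )
        samples.append(TissueSample(name, float(hu.data[eroded].mean()), n,
                                    float(assumed_densities[name])))
    return samples


def fit_phantomless(samples: list[TissueSample], include_air: bool = False,
                    air_sample: TissueSample | None = None) -> CalibrationLine:
    """OLS fit of assumed density on mean HU over the tissue samples.

    Air participates only if ``include_air`` is set and an ``air_sample``
    with an assumed density is supplied; the default uses air purely as a
    range check elsewhere.
    """
    pts = list(samples)
    if include_air and air_sample is not None:
        pts.append(air_sample)
    if len(pts) < 2:
        raise ValueError("need at least two tissue samples to fit a line")
    x = np.array([s.mean_hu for s in pts])
    y = np.array([s.assumed_density for s in pts])
    return _ols_line(x, y, source="phantomless")


def fit_phantom(hu: Volume, rod_labels: Volume, spec: PhantomSpec,
                erosion_voxels: int = 2) -> CalibrationLine:
    """OLS fit of nominal rod density on eroded rod mean HU (5-rod phantom)."""
    missing = []
    x = []
    for i, dens in enumerate(spec.rod_densities, start=1):
        region = rod_labels.data == i
        if not region.any():
            missing.append(i)
            continue
        eroded = erode_ball(region, erosion_voxels)
        if not eroded.any():
            eroded = region  # thin rods: fall back to the raw mask
        x.append(float(hu.data[eroded].mean()))
    if missing:
        raise PartialPhantomError(f"phantom rods missing from the scan: {missing}")
    return _ols_line(np.array(x), np.array(spec.rod_densities), source="phantom")


def _ols_line(x: np.ndarray, y: np.ndarray, source: str) -> CalibrationLine:
    if np.ptp(x) == 0:
        raise SingularFitError("all reference regions share one mean HU; cannot fit a line")
    if len(x) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    return CalibrationLine(float(slope), float(intercept), float(min(r2, 1.0)),
                           source, n_points=len(x))


def apply_calibration(hu: Volume, line: CalibrationLine) -> Volume:
    """Voxel-wise affine map to K2HPO4-equivalent density (mg/cm³), unclamped."""
    out = hu.copy_with(line.slope * hu.data.astype(float) + line.intercept)
    out.meta["units"] = "mg/cm3 K2HPO4"
    return out


def measure_vbmd(density: Volume, body_mask: np.ndarray, erosion_voxels: int = 5) -> float:
    """Volumetric BMD (mg/cm³): mean calibrated density over the eroded body
    mask, excluding the dense cortical shell and partial-volume rim."""
    eroded = erode_ball(np.asarray(body_mask, dtype=bool), erosion_voxels)
    if not eroded.any():
        raise RegionErodedAwayError(
            f"vertebral body mask vanished under a {erosion_voxels}-voxel erosion"
        )
    return float(density.data[eroded].mean())


def compare_calibrations(a, b) -> AgreementReport:
    """Agreement between two paired vBMD (or strength) series.

    Pearson r plus Bland-Altman mean difference (a - b) and 1.96-SD limits.
    With zero variance in either series the correlation is undefined and the
    report is flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D series")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    degenerate = bool(a.std() == 0 or b.std() == 0)
    if degenerate:
        r = np.nan
        warnings.warn("zero variance in one series: Pearson r undefined", stacklevel=2)
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return AgreementReport(r, mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd,
                           n=len(a), degenerate=degenerate)
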
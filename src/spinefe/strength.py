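"""Vertebral failure-load estimators.

Three strength surrogates are computed per vertebra:

* ``rforce_linear`` — reaction force of a single linear-elastic solve at a
  small apparent strain (default 0.2%), the displacement-calibrated linear
  surrogate;
* ``fload_stiffness`` — the column-model estimate
  ``F = 0.0068 * K_FE * H`` from the model stiffness ``K_FE`` (kN/mm) and
  the vertebral height ``H`` (mm);
* ``fload_nonlinear`` — the force on the elastoplastic force-displacement
  curve at 2% apparent strain (the nonlinear failure load).

The displacement threshold of the linear surrogate can be recalibrated
from a few representative vertebrae by least-squares matching of linear
reaction forces to nonlinear failure loads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fe import FDCurve
from .volume import Volume

__all__ = [
    "FEModelConfig",
    "StrengthRecord",
    "fload_stiffness",
    "fload_nonlinear",
    "vertebral_height",
    "calibrate_displacement_threshold",
]


@dataclass
class FEModelConfig:
    """All solver and estimator constants in one place."""

    linear_strain: float = 0.002        # apparent strain of the linear solve
    nonlinear_strain: float = 0.02      # target strain of the plastic solve
    yield_strain_factor: float = 0.0068  # column-model constant
    n_bins: int = 256
    tol: float = 1e-6
    max_linear_iter: int = 30000
    max_plastic_iter: int = 10000
    n_increments: int = 20
    nu: float = 0.3
    pmma_thickness_voxels: int = 3
    density_floor: float = 0.005        # g/cm³
    resample_mm: float = 1.0

    def __post_init__(self):
        if self.linear_strain <= 0 or self.nonlinear_strain <= 0:
            raise ValueError("strains must be positive")
        if self.linear_strain >= self.nonlinear_strain:
            raise ValueError("linear strain must be below the nonlinear target strain")
        for name in ("yield_strain_factor", "n_bins", "tol", "max_linear_iter",
                     "max_plastic_iter", "n_increments", "nu",
                     "density_floor", "resample_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StrengthRecord:
    subject: str
    level: str
    method: str                         # rforce_linear | fload_stiffness | fload_nonlinear
    value: float                        # kN
    H: float                            # mm, vertebral (body) height
    K_FE: float = np.nan                # kN/mm
    converged: bool = True

    def __post_init__(self):
        if self.H <= 0:
            raise ValueError("vertebral height must be positive")
        if self.converged and self.value < 0:
            raise ValueError("negative strength for a converged solve")


def fload_stiffness(K_FE: float, H: float, factor: float = 0.0068) -> float:
    """Column-model failure load (kN): ``factor * K_FE * H``."""
    if K_FE <= 0 or H <= 0:
        raise ValueError("stiffness and height must be positive")
    if factor < 0:
        raise ValueError("yield strain factor must be >= 0")
    return factor * K_FE * H


def fload_nonlinear(curve: FDCurve, target_strain: float = 0.02,
                    rtol: float = 1e-9) -> float:
    """Failure load (kN): force at the target apparent strain on the curve.

    Increments are laid out to land exactly on the target; a curve truncated
    by non-convergence before the target raises, reporting the last
    converged strain.
    """
    s = curve.apparent_strain
    hit = np.isclose(s, target_strain, rtol=rtol, atol=1e-12)
    if not hit.any():
        last = s[-1] if len(s) else 0.0
        raise ValueError(
            f"curve does not reach {target_strain:.4%} apparent strain "
            f"(last converged: {last:.4%})"
        )
    return float(curve.force[np.argmax(hit)])


def vertebral_height(mask: Volume | np.ndarray, spacing: float | None = None) -> float:
    """Vertebral body height H (mm): craniocaudal extent of the body mask."""
    if isinstance(mask, Volume):
        data = mask.data.astype(bool)
        spacing = mask.spacing[2]
    else:
        data = np.asarray(mask, dtype=bool)
        if spacing is None:
            raise ValueError("spacing required for a bare array")
    zs = np.nonzero(data.any(axis=(0, 1)))[0]
    if len(zs) == 0:
        raise ValueError("empty mask")
    return float((zs.max() - zs.min() + 1) * spacing)


def calibrate_displacement_threshold(samples) -> float:
    """Apparent-strain threshold u* for the linear surrogate.

    ``samples`` is a list of ``(K_FE kN/mm, F_nonlinear kN, H_loaded mm)``.
    Minimizes the summed squared relative error
    ``sum_i ((K_i * u * H_i - F_i) / F_i)^2``, which has the closed form
    ``u* = sum(a_i) / sum(a_i^2)`` with ``a_i = K_i * H_i / F_i``; a single
    sample gives exactly ``F / (K * H)``.
    """
    a = []
    for k, f_nl, h in samples:
        if k <= 0:
            continue
        if f_nl <= 0 or h <= 0:
            raise ValueError("failure load and height must be positive")
        a.append(k * h / f_nl)
    if not a:
        raise ValueError("no sample with positive stiffness")
    a = np.asarray(a)
    return float(a.sum() / (a**2).sum())
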
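"""Density-driven material laws and the binned material table.

Bone elements get isotropic linear-elastic (and optionally elastic-perfectly-
plastic) properties from the calibrated apparent density ``rho_qct`` (g/cm³)
through two power laws established for clinical-resolution QCT:

    E (MPa)       = 2980 * rho^1.05        (density–modulus)
    sigma_y (MPa) = 37.4 * rho^1.39        (density–yield stress)

Poisson's ratio is 0.3 for all bone.  Continuous density is approximated by a
fixed number of equal-width bins (default 256) whose properties are evaluated
at the bin midpoint.  PMMA cap material has fixed properties (E = 2500 MPa,
sigma_y = 70 MPa, nu = 0.3) and lives outside the bone bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "elastic_modulus",
    "yield_stress",
    "MaterialTable",
    "assign_materials",
    "PMMA_E",
    "PMMA_SIGMA_Y",
    "PMMA_NU",
    "BONE_NU",
    "PMMA_MATERIAL_ID",
]

#: Density–modulus power law coefficients (MPa, density in g/cm³).
MODULUS_COEFF = 2980.0
MODULUS_EXP = 1.05
#: Density–yield power law coefficients (MPa, density in g/cm³).
YIELD_COEFF = 37.4
YIELD_EXP = 1.39

BONE_NU = 0.3
PMMA_E = 2500.0
PMMA_SIGMA_Y = 70.0
PMMA_NU = 0.3

#: Material id reserved for PMMA cap elements (bone bins are 0..n_bins-1).
PMMA_MATERIAL_ID = -1


def elastic_modulus(rho_qct):
    """Elastic modulus in MPa for calibrated apparent density in g/cm³."""
    return MODULUS_COEFF * np.power(rho_qct, MODULUS_EXP)


def yield_stress(rho_qct):
    """Yield stress in MPa for calibrated apparent density in g/cm³."""
    return YIELD_COEFF * np.power(rho_qct, YIELD_EXP)


@dataclass
class MaterialTable:
    """Per-bin material properties plus the fixed PMMA entry.

    ``element_material`` holds one id per element: ``0..n_bins-1`` for bone,
    :data:`PMMA_MATERIAL_ID` for PMMA caps.
    """

    rho_bin: np.ndarray          # bin-midpoint density, g/cm³
    E: np.ndarray                # MPa, per bin
    sigma_y: np.ndarray          # MPa, per bin
    nu: float = BONE_NU
    pmma: tuple[float, float, float] = (PMMA_E, PMMA_SIGMA_Y, PMMA_NU)
    element_material: np.ndarray = field(default=None)

    @property
    def n_bins(self) -> int:
        return len(self.rho_bin)

    def element_modulus(self) -> np.ndarray:
        """E per element (MPa), resolving bone bins and PMMA."""
        return self._lookup(self.E, self.pmma[0])

    def element_yield(self, rigid: bool = False) -> np.ndarray:
        """sigma_y per element (MPa); ``rigid=True`` returns +inf everywhere
        (pure elastic limit of the elastoplastic solver)."""
        if rigid:
            return np.full(len(self.element_material), np.inf)
        return self._lookup(self.sigma_y, self.pmma[1])

    def _lookup(self, per_bin: np.ndarray, pmma_value: float) -> np.ndarray:
        ids = self.element_material
        out = np.empty(len(ids), dtype=float)
        bone = ids >= 0
        out[bone] = per_bin[ids[bone]]
        out[~bone] = pmma_value
        return out


def assign_materials(element_density: np.ndarray, n_bins: int = 256,
                     pmma_elements: np.ndarray | None = None) -> MaterialTable:
    """Bin element densities and evaluate the power laws at bin midpoints.

    Parameters
    ----------
    element_density:
        Apparent density per element in g/cm³ (bone elements; values for
        PMMA elements are ignored).
    n_bins:
        Number of equal-width density bins spanning [min, max] of the bone
        densities.
    pmma_elements:
        Optional boolean array flagging PMMA cap elements.
    """
    rho = np.asarray(element_density, dtype=float)
    if pmma_elements is None:
        pmma_elements = np.zeros(len(rho), dtype=bool)
    bone = ~pmma_elements
    if not bone.any():
        raise ValueError("mesh contains no bone elements")
    rho_bone = rho[bone]
    if np.any(rho_bone <= 0):
        raise ValueError("bone element densities must be positive (apply the density floor first)")

    lo, hi = float(rho_bone.min()), float(rho_bone.max())
    if hi == lo:
        edges = np.array([lo - 0.5e-12, hi + 0.5e-12])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    ids = np.full(len(rho), PMMA_MATERIAL_ID, dtype=np.int64)
    bone_bins = np.clip(np.searchsorted(edges, rho_bone, side="right") - 1, 0, n_bins - 1)
    ids[bone] = bone_bins

    table = MaterialTable(
        rho_bin=mids,
        E=elastic_modulus(mids),
        sigma_y=yield_stress(mids),
        element_material=ids,
    )
    return table
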